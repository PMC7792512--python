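"""Habitat-effect statistics: linear models, Tukey HSD letters, Pearson r.

The habitat effect on a per-site response (richness, evenness,
centrality) is estimated with ordinary least squares under treatment
(dummy) coding against a chosen reference habitat, so the intercept is
the reference-habitat mean and each coefficient is a difference of
habitat means. All-pairs comparisons use Tukey's HSD on the pooled error
variance, summarized as a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["LinearModelFit", "fit_habitat_lm", "tukey_letters", "pearson"]


@dataclass(frozen=True)
class LinearModelFit:
    """OLS fit of response ~ habitat with treatment coding."""

    response: str
    reference: str
    table: pd.DataFrame  # term, estimate, se, t, p
    df_resid: int
    values: np.ndarray
    groups: np.ndarray

    def coefficient(self, term: str) -> float:
        row = self.table.loc[self.table["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r}; have {self.table['term'].tolist()}")
        return float(row["estimate"].iloc[0])


def fit_habitat_lm(
    values: Sequence[float],
    habitats: Sequence[str],
    reference: str | None = None,
    response: str = "response",
) -> LinearModelFit:
    """OLS of a per-site value on habitat type with a chosen reference level.

    The intercept estimates the reference habitat's mean; each habitat
    coefficient is that habitat's mean minus the reference mean, with a
    two-sided t-test. ``reference`` defaults to the habitat with most
    sites.
    """
    values = np.asarray(values, dtype=float)
    habitats = np.asarray([str(h) for h in habitats])
    if values.shape != habitats.shape:
        raise ValueError("values and habitat labels differ in length")
    levels = pd.unique(habitats)
    if len(levels) < 2:
        raise ValueError("need at least two habitat levels")
    if np.ptp(values) == 0:
        raise ValueError("constant response: degenerate fit")
    if reference is None:
        counts = pd.Series(habitats).value_counts()
        reference = str(counts.index[0])
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among {list(levels)}")
    df = pd.DataFrame({"y": values, "habitat": habitats})
    fit = smf.ols(f"y ~ C(habitat, Treatment(reference='{reference}'))", df).fit()
    terms = []
    for name, est, se, t, p in zip(
        fit.params.index, fit.params, fit.bse, fit.tvalues, fit.pvalues
    ):
        if name == "Intercept":
            label = f"Intercept ({reference})"
        else:  # C(habitat, Treatment(reference='x'))[T.level]
            label = name.split("[T.", 1)[1].rstrip("]")
        terms.append(
            {"term": label, "estimate": est, "se": se, "t": t, "p": p}
        )
    return LinearModelFit(
        response=response,
        reference=reference,
        table=pd.DataFrame(terms),
        df_resid=int(fit.df_resid),
        values=values,
        groups=habitats,
    )


def tukey_letters(fit: LinearModelFit, level: float = 0.05) -> dict[str, str]:
    """Compact letter display from all-pairs Tukey HSD at the given level.

    Habitats sharing no letter differ significantly. Letters are maximal
    cliques of the "not significantly different" graph, ordered by
    decreasing group mean.
    """
    groups = pd.unique(fit.groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups for Tukey HSD")
    hsd = pairwise_tukeyhsd(fit.values, fit.groups, alpha=level)
    res = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    g = nx.Graph()
    g.add_nodes_from(groups)
    for _, row in res.iterrows():
        if not row["reject"]:
            g.add_edge(row["group1"], row["group2"])
    means = {h: fit.values[fit.groups == h].mean() for h in groups}
    cliques = sorted(
        nx.find_cliques(g), key=lambda c: -max(means[h] for h in c)
    )
    letters: dict[str, str] = {h: "" for h in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for h in clique:
            letters[h] += letter
    return {h: "".join(sorted(letters[h])) for h in groups}


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
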