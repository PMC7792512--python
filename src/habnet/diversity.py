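"""Per-site diversity indices: species richness and Smith-Wilson evenness.

Richness S is the number of species observed at a site. Evenness is the
Smith & Wilson E_var index,

    E_var = 1 - (2/pi) * arctan( Var[ln n_s] ),

where the variance is taken over the S observed species' log abundances.
E_var is 1 for a perfectly even community and decreases towards 0 as the
abundance distribution becomes more skewed; unlike many evenness indices
it is independent of richness and of rescaling all abundances.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import AbundanceMatrix

__all__ = ["richness", "evar", "diversity_table"]


def richness(counts: np.ndarray) -> int:
    """Number of species with count > 0 at one site."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count vector")
    return int((counts > 0).sum())


def evar(counts: np.ndarray, ddof: int = 0) -> float:
    """Smith-Wilson E_var evenness of one site's abundance vector.

    Only species with positive counts enter the log-variance. ``ddof=0``
    (population variance, divide by S) is the conventional form; the
    sample-variance form is available with ``ddof=1``. A single observed
    species has zero log-variance, hence E_var = 1.
    """
    counts = np.asarray(counts, dtype=float)
    pos = counts[counts > 0]
    if pos.size == 0:
        raise ValueError("evenness undefined for an all-zero count vector")
    if pos.size == 1:
        return 1.0
    var = np.var(np.log(pos), ddof=ddof)
    return 1.0 - (2.0 / math.pi) * math.atan(var)


def diversity_table(mat: AbundanceMatrix, ddof: int = 0) -> pd.DataFrame:
    """Per-site richness, E_var and abundance, with habitat labels.

    Returns one row per site: ``site, habitat, richness, evar, abundance``.
    """
    rows = []
    for i, site in enumerate(mat.site_ids):
        c = mat.counts[i]
        rows.append(
            {
                "site": site,
                "habitat": mat.habitat_of[site],
                "richness": richness(c),
                "evar": evar(c, ddof=ddof),
                "abundance": int(c.sum()),
            }
        )
    return pd.DataFrame(rows)
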