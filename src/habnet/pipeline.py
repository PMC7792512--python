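"""One-command pipeline: matrix in, full analysis bundle out.

Stages run in a fixed order — diversity, bipartite metrics with
Patefield nulls, unipartite projection, centrality, community detection,
habitat-effect models — but every stage is a pure function of the input
matrix, so the order has no effect on any reported number. A single
global seed fans out into independent per-stage seeds through
``numpy.random.SeedSequence``, so adding a stage never perturbs earlier
stages' random streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bipartite as bp
from . import diversity as dv
from . import stats as st
from . import unipartite as up
from .core import AbundanceMatrix, build_bipartite, project_unipartite

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    input_path: str
    out_dir: str
    n_nulls: int = 1000
    n_nulls_modularity: int | None = None
    alpha: float = 0.5
    seed: int = 0
    reference: str | None = None  # habitat reference level; None = most sites
    algorithms: tuple[str, ...] = ("multilevel", "walktrap", "spinglass")
    n_restarts: int = 20
    null_restarts: int = 5
    drop_empty: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_nulls < 0 or self.n_restarts < 1:
            raise ValueError("replicate and restart counts must be positive")
        unknown = set(self.algorithms) - set(up.ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithm(s) {sorted(unknown)}")


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [
        int(c.generate_state(1)[0] % 2**31)
        for c in np.random.SeedSequence(seed).spawn(n)
    ]


def run_pipeline(
    config: RunConfig, mat: AbundanceMatrix | None = None
) -> dict:
    """Run every analysis stage and write the report bundle to ``out_dir``.

    Returns the metrics dictionary that is also written to
    ``metrics.json``. Identical config (and input) gives a byte-identical
    bundle.
    """
    from .core import read_abundance_matrix

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if mat is None:
        mat = read_abundance_matrix(config.input_path, drop_empty=config.drop_empty)

    s_bip, s_comm = _stage_seeds(config.seed, 2)

    # diversity ----------------------------------------------------------
    div = dv.diversity_table(mat)
    div.to_csv(out / "diversity.csv", index=False)

    # bipartite architecture + nulls -------------------------------------
    net = build_bipartite(mat)
    metrics = bp.compute_metrics(
        net,
        n_nulls=config.n_nulls,
        n_nulls_modularity=config.n_nulls_modularity,
        seed=s_bip,
        n_restarts=config.n_restarts,
        null_restarts=config.null_restarts,
    )
    metrics.partition.to_frame().to_csv(out / "bipartite_modules.csv", index=False)
    pd.DataFrame({"x": metrics.curve.x, "y": metrics.curve.y}).to_csv(
        out / "extinction_curve.csv", index=False
    )

    # unipartite projection ----------------------------------------------
    uni = project_unipartite(net)
    cent = up.weighted_degree_centrality(uni, alpha=config.alpha)
    cent.to_csv(out / "centrality.csv", index=False)

    partitions = {}
    for algo in config.algorithms:
        # seed keyed to the algorithm's identity, not its position in the
        # requested list, so reordering algorithms changes nothing
        part = up.detect_communities(
            uni, algorithm=algo, seed=s_comm + up.ALGORITHMS.index(algo)
        )
        partitions[algo] = part
        part.to_frame().to_csv(out / f"communities_{algo}.csv", index=False)
    mixing = None
    if "multilevel" in partitions:
        mixing = up.mixing_parameter(uni, partitions["multilevel"])
        with open(out / "mixing.json", "w") as fh:
            json.dump(
                {k: v for k, v in mixing.items() if not isinstance(v, dict)},
                fh,
                indent=1,
                sort_keys=True,
            )

    # habitat-effect models ----------------------------------------------
    div = div.merge(cent[["patch", "centrality"]], left_on="site", right_on="patch")
    lm_results = {}
    for response in ("richness", "evar", "centrality"):
        fit = st.fit_habitat_lm(
            div[response], div["habitat"], reference=config.reference,
            response=response,
        )
        fit.table.to_csv(out / f"lm_{response}.csv", index=False)
        letters = st.tukey_letters(fit)
        pd.DataFrame(
            {"habitat": list(letters), "letters": list(letters.values())}
        ).to_csv(out / f"tukey_{response}.csv", index=False)
        lm_results[response] = fit

    r_rich, p_rich = st.pearson(div["centrality"], div["richness"])
    r_evar, p_evar = st.pearson(div["centrality"], div["evar"])

    report = {
        "n_sites": mat.n_sites,
        "n_species": mat.n_species,
        "total_individuals": mat.total_individuals,
        "connectance": metrics.connectance,
        "weighted_nodf": metrics.weighted_nodf,
        "weighted_nodf_z": metrics.wnodf_z,
        "modularity": metrics.modularity,
        "modularity_z": metrics.modularity_z,
        "modularity_excess": (
            None
            if metrics.modularity_null is None
            else metrics.modularity - metrics.modularity_null.mean
        ),
        "modularity_n_modules": metrics.partition.n_communities,
        "robustness": metrics.robustness,
        "n_nulls": config.n_nulls,
        "n_nulls_modularity": (
            config.n_nulls
            if config.n_nulls_modularity is None
            else config.n_nulls_modularity
        ),
        "alpha": config.alpha,
        "centrality_mean": float(cent["centrality"].mean()),
        "centrality_min": float(cent["centrality"].min()),
        "centrality_max": float(cent["centrality"].max()),
        "pearson_centrality_richness": {"r": r_rich, "p": p_rich},
        "pearson_centrality_evenness": {"r": r_evar, "p": p_evar},
        "communities": {a: p.n_communities for a, p in partitions.items()},
        "community_modularity": {a: p.quality for a, p in partitions.items()},
        "mixing": None
        if mixing is None
        else {"mu_degree": mixing["mu_degree"], "mu_strength": mixing["mu_strength"]},
        "seed": config.seed,
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
    return report
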