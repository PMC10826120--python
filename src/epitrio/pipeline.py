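"""Three-way interaction prioritization over a selected SNP panel.

Stages, in order: enumerate all C(m,3) triplets of the panel, screen them
with the chi-square(1 df) test on the three-way interaction-information
gain (IIG), exclude triplets any of whose pairs shows a significant
two-way information gain (the surviving interactions cannot be explained
at second order), exclude triplets containing a pair in strong linkage
disequilibrium (genotype-correlation r^2), and validate the survivors by
label-shuffling permutation testing.  ``run_pipeline`` chains the allelic
filter and the RF-RF selection in front of these stages and writes
tabular reports.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from .entropy import (
    InteractionStat,
    StratifiedCounts,
    info_gain,
    interaction_stat,
    lambda_variance,
    stratified_counts,
    test_statistic,
)
from .plinkio import CaseControlLabels, GenotypeMatrix, read_plink, subset_snps
from .rfsel import RFConfig, two_step_select

__all__ = [
    "PipelineConfig",
    "TripletResult",
    "enumerate_triplets",
    "screen_triplets",
    "pairwise_exclusion",
    "ld_exclusion",
    "permutation_test",
    "unique_snps",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and permutation settings of the triplet stages.

    ``n_perm`` of 1000 with ``perm_alpha`` 0.05 suits panels of tens of
    triplets; 10000 with 0.01 is the stricter large-panel setting.
    """

    triplet_alpha: float = 0.05
    pair_alpha: float = 0.05
    ld_r2_max: float = 0.8
    n_perm: int = 1000
    perm_alpha: float = 0.05
    reference: str = "controls"  # or "pooled": the 'general population' term
    pseudocount: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.triplet_alpha, self.pair_alpha, self.perm_alpha):
            if not 0 <= p <= 1:
                raise ValueError("alphas must lie in [0, 1]")
        if not 0 <= self.ld_r2_max <= 1:
            raise ValueError("ld_r2_max must lie in [0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class TripletResult:
    """One candidate triplet through the prioritization cascade."""

    snp_ids: tuple[str, str, str]
    iig: float
    lambda_norm: float
    t_stat: float
    p_chi2: float
    p_perm: float | None = None
    excluded_reason: str = "none"  # none | pairwise_2way | ld_pair
    direction: str = "zero"  # positive | negative | zero
    pair_stats: list[InteractionStat] = field(default_factory=list)
    significant: bool | None = None

    @property
    def surviving(self) -> bool:
        return self.excluded_reason == "none"


def enumerate_triplets(snp_ids: list[str]) -> list[tuple[str, str, str]]:
    """All C(m,3) unordered triplets, lexicographic in the input order."""
    if len(snp_ids) < 3:
        raise ValueError("need at least 3 SNP ids to form triplets")
    if len(set(snp_ids)) != len(snp_ids):
        raise ValueError("duplicate SNP ids")
    return list(combinations(snp_ids, 3))


def _direction(gain: float) -> str:
    if gain > 0:
        return "positive"
    if gain < 0:
        return "negative"
    return "zero"


def screen_triplets(
    g: GenotypeMatrix,
    labels: CaseControlLabels,
    triplets: list[tuple[str, str, str]],
    cfg: PipelineConfig,
) -> list[TripletResult]:
    """Chi-square screen: keep triplets with IIG-test p below triplet_alpha."""
    labels.require_both_classes()
    out = []
    for trip in triplets:
        sc = stratified_counts(g, labels, trip)
        if sc.case_counts.sum() == 0 or sc.control_counts.sum() == 0:
            logger.warning("triplet %s skipped: empty stratum", trip)
            continue
        st = interaction_stat(sc, reference=cfg.reference, pseudocount=cfg.pseudocount)
        if st.p_chi2 < cfg.triplet_alpha:
            out.append(
                TripletResult(
                    snp_ids=tuple(trip),
                    iig=st.gain,
                    lambda_norm=st.lambda_norm,
                    t_stat=st.t_stat,
                    p_chi2=st.p_chi2,
                    direction=_direction(st.gain),
                )
            )
    return out


def pairwise_exclusion(
    results: list[TripletResult],
    g: GenotypeMatrix,
    labels: CaseControlLabels,
    cfg: PipelineConfig,
) -> list[TripletResult]:
    """Flag triplets containing a pair with significant two-way IG."""
    for res in results:
        if not res.surviving:
            continue
        res.pair_stats = []
        excluded = False
        for pair in combinations(res.snp_ids, 2):
            sc = stratified_counts(g, labels, pair)
            st = interaction_stat(
                sc, reference=cfg.reference, pseudocount=cfg.pseudocount
            )
            res.pair_stats.append(st)
            if st.p_chi2 < cfg.pair_alpha:
                excluded = True
        if excluded:
            res.excluded_reason = "pairwise_2way"
    return results


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of 0/1/2 codes.

    Computed over individuals non-missing at both SNPs; a zero-variance
    SNP yields r^2 = 0 with a warning.
    """
    ok = (x >= 0) & (y >= 0)
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if len(xs) < 2 or xs.std() == 0 or ys.std() == 0:
        warnings.warn("zero-variance SNP in LD computation; r^2 set to 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_exclusion(
    results: list[TripletResult], g: GenotypeMatrix, cfg: PipelineConfig
) -> list[TripletResult]:
    """Flag surviving triplets containing a pair with r^2 above ld_r2_max."""
    cache: dict[tuple[str, str], float] = {}
    for res in results:
        if not res.surviving:
            continue
        for pair in combinations(res.snp_ids, 2):
            key = tuple(sorted(pair))
            if key not in cache:
                cache[key] = genotype_r2(g.column(key[0]), g.column(key[1]))
            if cache[key] > cfg.ld_r2_max:
                res.excluded_reason = "ld_pair"
                break
    return results


def _triplet_T(
    case_counts: np.ndarray, ctrl_counts: np.ndarray, cfg: PipelineConfig, ids
) -> float:
    sc = StratifiedCounts(ids, case_counts, ctrl_counts)
    gain = info_gain(sc, reference=cfg.reference, pseudocount=cfg.pseudocount)
    lam = lambda_variance(sc, reference=cfg.reference, pseudocount=cfg.pseudocount)
    t, _p = test_statistic(gain, lam)
    return t


def permutation_test(
    g: GenotypeMatrix,
    labels: CaseControlLabels,
    results: list[TripletResult],
    cfg: PipelineConfig,
) -> list[TripletResult]:
    """Label-shuffling permutation p-values for surviving triplets.

    One shuffle per iteration scores every triplet (shared permutations);
    ``p_perm = (1 + #{T_perm >= T_obs}) / (1 + n_perm)``, and a triplet is
    significant when ``p_perm < perm_alpha``.
    """
    surviving = [r for r in results if r.surviving]
    if not surviving:
        raise ValueError("no surviving triplets to permute")
    rng = np.random.default_rng(cfg.seed)

    # per-triplet flattened genotype-cell index with tuple-wise deletion
    cells, masks = [], []
    for res in surviving:
        cols = np.column_stack([g.column(s) for s in res.snp_ids])
        ok = (cols >= 0).all(axis=1)
        idx = (cols[ok, 0] * 9 + cols[ok, 1] * 3 + cols[ok, 2]).astype(np.int64)
        cells.append(idx)
        masks.append(ok)

    exceed = np.zeros(len(surviving), dtype=np.int64)
    status = labels.status
    for _b in range(cfg.n_perm):
        perm = rng.permutation(status)
        for i, res in enumerate(surviving):
            s = perm[masks[i]]
            case = np.bincount(cells[i][s == 1], minlength=27).reshape(3, 3, 3)
            ctrl = np.bincount(cells[i][s == 0], minlength=27).reshape(3, 3, 3)
            if case.sum() == 0 or ctrl.sum() == 0:
                continue
            t_perm = _triplet_T(case, ctrl, cfg, res.snp_ids)
            if t_perm >= res.t_stat:
                exceed[i] += 1
    for i, res in enumerate(surviving):
        res.p_perm = float((1 + exceed[i]) / (1 + cfg.n_perm))
        res.significant = res.p_perm < cfg.perm_alpha
    return results


def unique_snps(results, only_significant: bool = False) -> list[str]:
    """Sorted distinct SNP ids over the (optionally significant) triplets.

    Accepts :class:`TripletResult` records or bare id-triples.
    """
    ids: set[str] = set()
    for item in results:
        if hasattr(item, "snp_ids"):
            if only_significant and not item.significant:
                continue
            ids.update(item.snp_ids)
        else:
            ids.update(item)
    return sorted(ids)


def results_frame(results: list[TripletResult]) -> pd.DataFrame:
    """Tabular report: one row per triplet, final-report column layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "SNP1": r.snp_ids[0],
                "SNP2": r.snp_ids[1],
                "SNP3": r.snp_ids[2],
                "IIG": r.iig,
                "T_IG": r.t_stat,
                "P": r.p_chi2,
                "PERM_P": r.p_perm if r.p_perm is not None else np.nan,
                "DIRECTION": r.direction,
                "EXCLUDED_REASON": r.excluded_reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "SNP1", "SNP2", "SNP3", "IIG", "T_IG", "P",
            "PERM_P", "DIRECTION", "EXCLUDED_REASON",
        ],
    )


def run_pipeline(
    source: str | Path | tuple[GenotypeMatrix, CaseControlLabels],
    assoc_alpha: float = 0.01,
    rf_config: RFConfig | None = None,
    triplet_config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """End-to-end prioritization: allelic filter -> RF-RF -> triplet cascade.

    ``source`` is a PLINK prefix or an in-memory ``(genotypes, labels)``
    pair.  Returns a report bundle with per-stage outputs; any stage
    yielding too small a set terminates the run cleanly with the stage
    named in ``report["terminated_at"]``.  When ``out_dir`` is given,
    per-stage TSVs and a JSON summary are written there.
    """
    rf_config = rf_config or RFConfig()
    cfg = triplet_config or PipelineConfig()
    if isinstance(source, (str, Path)):
        g, labels = read_plink(source)
    else:
        g, labels = source
    labels.require_both_classes()

    report: dict = {
        "config": {
            "assoc_alpha": assoc_alpha,
            "rf": vars(rf_config).copy(),
            "triplets": vars(cfg).copy(),
        },
        "n_individuals": g.n_individuals,
        "n_snps": g.n_snps,
        "terminated_at": None,
        "results": [],
        "significant": [],
    }

    assoc_results = assoc_mod.allelic_test_all(g, labels)
    assoc_kept = assoc_mod.filter_by_p(assoc_results, alpha=assoc_alpha)
    report["assoc_kept"] = assoc_kept
    if len(assoc_kept) < 3:
        report["terminated_at"] = "assoc_filter"
        _write_outputs(report, assoc_results, g, out_dir)
        return report

    g_assoc = subset_snps(g, assoc_kept)
    rf_res = two_step_select(g_assoc, labels, rf_config)
    report["rf_selected"] = list(rf_res.selected_ids)
    report["rf_cv_error"] = rf_res.cv_error
    if len(rf_res.selected_ids) < 3:
        report["terminated_at"] = "rf_prioritizer"
        _write_outputs(report, assoc_results, g, out_dir)
        return report

    triplets = enumerate_triplets(rf_res.selected_ids)
    results = screen_triplets(g, labels, triplets, cfg)
    report["n_triplets_enumerated"] = len(triplets)
    report["n_triplets_screened"] = len(results)
    if not results:
        report["terminated_at"] = "triplet_screen"
        _write_outputs(report, assoc_results, g, out_dir)
        return report

    results = pairwise_exclusion(results, g, labels, cfg)
    results = ld_exclusion(results, g, cfg)
    if not any(r.surviving for r in results):
        report["terminated_at"] = "exclusions"
        report["results"] = results
        _write_outputs(report, assoc_results, g, out_dir)
        return report

    results = permutation_test(g, labels, results, cfg)
    report["results"] = results
    report["significant"] = [r for r in results if r.surviving and r.significant]
    report["unique_significant_snps"] = unique_snps(
        report["significant"], only_significant=False
    )
    _write_outputs(report, assoc_results, g, out_dir)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(o) for o in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_outputs(report: dict, assoc_results, g, out_dir) -> None:
    if out_dir is None:
        return
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assoc_mod.write_assoc_tsv(assoc_results, g, out_dir / "assoc.tsv")
    results = report.get("results") or []
    if results:
        results_frame(results).to_csv(out_dir / "triplets.tsv", sep="\t", index=False)
        sig = [r for r in results if r.surviving and r.significant]
        if sig:
            results_frame(sig).to_csv(
                out_dir / "triplets_significant.tsv", sep="\t", index=False
            )
    summary = {
        k: _jsonable(v)
        for k, v in report.items()
        if k not in ("results", "significant")
    }
    summary["n_significant"] = len(
        [r for r in results if getattr(r, "significant", False)]
    )
    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
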