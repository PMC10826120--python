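"""Synthetic case-control genotype cohorts with known ground truth.

The generator emulates the ingredients a three-way-interaction screen has
to cope with: biallelic background SNPs in Hardy-Weinberg equilibrium,
optional LD blocks (latent-Gaussian haplotype correlation), SNPs with
marginal genotype relative risks, and planted penetrance-table triplets
whose case-control association is *purely* third order — no single-SNP and
no pairwise signal — so that recovery of the planted triplet is a genuine
parameter-recovery exercise rather than a marginal-effect shortcut.

Disease model: log-odds additive.  For individual genotype vector g,

    logit P(D=1) = logit(baseline)
                 + sum_j log RR_j(g_j)                    (marginal SNPs)
                 + sum_t [logit f_t(g_t) - logit fbar_t]  (planted triplets)

where ``fbar_t`` is the HWE-weighted mean of triplet t's penetrance table.
With a single pure triplet and ``baseline == fbar_t`` this reduces to
``P(D=1) = f_t(g_t)`` exactly, i.e. the table acts as an override on its
three SNPs.  Case/control quotas are filled by rejection sampling,
mirroring retrospective ascertainment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .plinkio import MISSING, CaseControlLabels, GenotypeMatrix

__all__ = [
    "PenetranceTriplet",
    "SimulationSpec",
    "make_parity_penetrance",
    "simulate_cohort",
    "fixture_small",
]

_HWE_CACHE: dict = {}


def _hwe_weights(maf: float) -> np.ndarray:
    """Genotype probabilities (q^2, 2pq, p^2) for codes (0, 1, 2).

    Code counts copies of the minor allele (frequency ``maf``), so code 2
    has probability maf^2.
    """
    q = 1.0 - maf
    return np.array([q * q, 2.0 * maf * q, maf * maf])


@dataclass
class PenetranceTriplet:
    """A planted three-locus disease model.

    ``penetrance[g1, g2, g3]`` is P(D=1 | genotypes), a 3x3x3 table.
    When ``purity`` is set, every single-SNP and pairwise marginal of the
    table under HWE genotype frequencies must be constant (tolerance
    1e-12): the association carries no first- or second-order signal.
    """

    mafs: tuple[float, float, float]
    penetrance: np.ndarray
    purity: bool = False

    def __post_init__(self) -> None:
        self.penetrance = np.asarray(self.penetrance, dtype=float).reshape(3, 3, 3)
        if ((self.penetrance < 0) | (self.penetrance > 1)).any():
            raise ValueError("penetrance entries must lie in [0, 1]")
        if self.purity:
            self._check_purity()

    def _weights(self) -> list[np.ndarray]:
        return [_hwe_weights(m) for m in self.mafs]

    def hwe_mean(self) -> float:
        """HWE-weighted mean penetrance (population prevalence of the table)."""
        w1, w2, w3 = self._weights()
        return float(np.einsum("ijk,i,j,k->", self.penetrance, w1, w2, w3))

    def single_marginals(self) -> list[np.ndarray]:
        """Per-SNP marginal penetrance, one length-3 vector per locus."""
        w = self._weights()
        f = self.penetrance
        out = []
        for axis in range(3):
            others = [a for a in range(3) if a != axis]
            m = np.tensordot(f, w[others[0]], axes=(others[0], 0))
            m = np.tensordot(m, w[others[1]], axes=(1 if others[1] > axis else 0, 0))
            out.append(m)
        return out

    def pair_marginals(self) -> list[np.ndarray]:
        """Pairwise marginal penetrance, one 3x3 table per locus pair."""
        w = self._weights()
        f = self.penetrance
        return [
            np.tensordot(f, w[2], axes=(2, 0)),  # (g1, g2)
            np.tensordot(f, w[1], axes=(1, 0)),  # (g1, g3)
            np.tensordot(f, w[0], axes=(0, 0)),  # (g2, g3)
        ]

    def _check_purity(self, tol: float = 1e-12) -> None:
        for m in self.single_marginals() + self.pair_marginals():
            if np.ptp(m) > tol:
                raise ValueError(
                    "purity violated: a lower-order marginal of the penetrance "
                    f"table varies by {np.ptp(m):.3g} (> {tol:g})"
                )


def make_parity_penetrance(
    mafs: Sequence[float] = (0.5, 0.5, 0.5),
    base: float = 0.1,
    effect: float = 0.05,
) -> PenetranceTriplet:
    """Parity (three-locus XOR-like) penetrance table.

    f(g1, g2, g3) = base + effect * (-1)^(g1+g2+g3).  At MAF 0.5 the
    genotype-code parity is a fair coin independent of any one or two of
    the codes, so all lower-order marginals equal ``base`` exactly: the
    table is a pure third-order signal.  At other MAFs parity is no longer
    balanced and the construction is only approximately pure, so the
    purity flag is set only when every MAF is 0.5.
    """
    mafs = tuple(float(m) for m in mafs)
    if base + effect > 1 or base - effect < 0:
        raise ValueError(
            f"base +/- effect must stay in [0, 1]; got base={base}, effect={effect}"
        )
    g = np.indices((3, 3, 3)).sum(axis=0)
    table = base + effect * np.where(g % 2 == 0, 1.0, -1.0)
    pure = all(m == 0.5 for m in mafs)
    return PenetranceTriplet(mafs=mafs, penetrance=table, purity=pure)


@dataclass
class SimulationSpec:
    """Full parameterization of a synthetic cohort.

    Defaults describe a mid-sized retrospective case-control panel:
    balanced quotas, background MAFs uniform on (0.05, 0.5), no missing
    calls, 10% baseline prevalence.
    """

    n_cases: int = 1000
    n_controls: int = 1000
    n_background_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    marginal_effects: list[tuple[float, tuple[float, float, float]]] = field(
        default_factory=list
    )
    planted_triplets: list[PenetranceTriplet] = field(default_factory=list)
    baseline_prevalence: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0
    max_attempt_batches: int = 500

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for p in (self.baseline_prevalence, self.missing_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for size, r in self.ld_blocks:
            if size < 2 or not 0 <= r < 1:
                raise ValueError("LD block needs size >= 2 and r in [0, 1)")


def _draw_ld_block(
    rng: np.random.Generator, n: int, size: int, r: float, mafs: np.ndarray
) -> np.ndarray:
    """Genotypes for one LD block via correlated latent Gaussian haplotypes."""
    thresh = norm.ppf(mafs)  # allele present when latent < threshold
    geno = np.zeros((n, size), dtype=np.int8)
    for _hap in range(2):
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, size))
        latent = np.sqrt(r) * shared + np.sqrt(1.0 - r) * noise
        geno += (latent < thresh).astype(np.int8)
    return geno


def _batch_genotypes(
    rng: np.random.Generator, n: int, spec: SimulationSpec, layout: dict
) -> np.ndarray:
    cols = []
    for maf in layout["bg_mafs"]:
        cols.append(rng.binomial(2, _HWE_p2(maf), size=n).astype(np.int8))
    for (size, r), mafs in zip(spec.ld_blocks, layout["ld_mafs"]):
        block = _draw_ld_block(rng, n, size, r, mafs)
        cols.extend(block.T)
    for maf, _rr in spec.marginal_effects:
        cols.append(rng.binomial(2, _HWE_p2(maf), size=n).astype(np.int8))
    for trip in spec.planted_triplets:
        for maf in trip.mafs:
            cols.append(rng.binomial(2, _HWE_p2(maf), size=n).astype(np.int8))
    return np.column_stack(cols) if cols else np.zeros((n, 0), dtype=np.int8)


def _HWE_p2(maf: float) -> float:
    # binomial(2, maf) gives exactly (q^2, 2pq, p^2) on codes (0,1,2)
    return maf


def _disease_prob(
    geno: np.ndarray, spec: SimulationSpec, layout: dict
) -> np.ndarray:
    lo = logit(np.clip(spec.baseline_prevalence, 1e-12, 1 - 1e-12))
    eta = np.full(geno.shape[0], lo)
    for (maf, rr), col in zip(spec.marginal_effects, layout["eff_cols"]):
        log_rr = np.log(np.asarray(rr, dtype=float))
        eta += log_rr[geno[:, col]]
    for trip, cols in zip(spec.planted_triplets, layout["trip_cols"]):
        f = np.clip(trip.penetrance, 1e-12, 1 - 1e-12)
        fbar = np.clip(trip.hwe_mean(), 1e-12, 1 - 1e-12)
        g1, g2, g3 = (geno[:, c] for c in cols)
        eta += logit(f[g1, g2, g3]) - logit(fbar)
    return expit(eta)


def _build_layout(spec: SimulationSpec, rng: np.random.Generator) -> dict:
    """Column order, ids and MAFs for every SNP class (fixed per cohort)."""
    lo, hi = spec.maf_range
    bg_mafs = rng.uniform(lo, hi, size=spec.n_background_snps)
    # one MAF per LD block: tightly linked SNPs share allele frequencies, and
    # frequency mismatch would cap the achievable genotype correlation
    ld_mafs = [
        np.full(size, rng.uniform(lo, hi)) for size, _r in spec.ld_blocks
    ]

    ids: list[str] = [f"rsbg{i:05d}" for i in range(spec.n_background_snps)]
    ld_ids = []
    for b, (size, _r) in enumerate(spec.ld_blocks):
        block_ids = [f"rsld{b}_{i}" for i in range(size)]
        ld_ids.append(block_ids)
        ids.extend(block_ids)
    eff_cols = []
    for j in range(len(spec.marginal_effects)):
        eff_cols.append(len(ids))
        ids.append(f"rseff{j}")
    trip_cols = []
    for t in range(len(spec.planted_triplets)):
        cols = [len(ids) + k for k in range(3)]
        trip_cols.append(cols)
        ids.extend(f"rstrip{t}_{k}" for k in range(3))
    return {
        "ids": ids,
        "bg_mafs": bg_mafs,
        "ld_mafs": ld_mafs,
        "ld_ids": ld_ids,
        "eff_cols": eff_cols,
        "trip_cols": trip_cols,
    }


def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[GenotypeMatrix, CaseControlLabels, dict]:
    """Simulate a cohort with exact case/control quotas.

    Returns the genotype matrix (cases first, then controls — rows are
    shuffled before return so ordering carries no signal), labels, and a
    ``truth`` record naming the planted triplet / marginal-effect / LD-block
    SNP ids and the realized MAFs.

    Raises ``RuntimeError`` if the case quota cannot be filled within
    ``spec.max_attempt_batches`` rejection-sampling batches (e.g. a
    near-zero penetrance model).
    """
    rng = np.random.default_rng(spec.seed)
    layout = _build_layout(spec, rng)

    need = {1: spec.n_cases, 0: spec.n_controls}
    kept_g = {0: [], 1: []}
    batch = max(2000, spec.n_cases + spec.n_controls)
    for _attempt in range(spec.max_attempt_batches):
        if need[0] <= 0 and need[1] <= 0:
            break
        geno = _batch_genotypes(rng, batch, spec, layout)
        prob = _disease_prob(geno, spec, layout)
        d = (rng.random(batch) < prob).astype(np.int8)
        for cls in (1, 0):
            if need[cls] > 0:
                take = geno[d == cls][: need[cls]]
                kept_g[cls].append(take)
                need[cls] -= len(take)
    if need[0] > 0 or need[1] > 0:
        raise RuntimeError(
            f"could not fill quotas after {spec.max_attempt_batches} batches; "
            f"still need {need[1]} cases, {need[0]} controls — "
            "check penetrance/prevalence settings"
        )

    values = np.vstack(
        [np.vstack(kept_g[1]), np.vstack(kept_g[0])]
    )
    status = np.concatenate(
        [np.ones(spec.n_cases, dtype=np.int8), np.zeros(spec.n_controls, dtype=np.int8)]
    )
    order = rng.permutation(len(status))
    values, status = values[order], status[order]

    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values[mask] = MISSING

    n_total = len(status)
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "snp_id": layout["ids"],
            "pos": np.arange(1, len(layout["ids"]) + 1) * 1000,
            "allele1": "A",
            "allele2": "G",
        }
    )
    individual_ids = [f"ind{i:06d}" for i in range(n_total)]
    g = GenotypeMatrix(values, meta, individual_ids)
    labels = CaseControlLabels(status)
    truth = {
        "planted_triplets": [
            [layout["ids"][c] for c in cols] for cols in layout["trip_cols"]
        ],
        "marginal_effect_snps": [layout["ids"][c] for c in layout["eff_cols"]],
        "ld_blocks": layout["ld_ids"],
        "background_mafs": [float(m) for m in layout["bg_mafs"]],
        "seed": spec.seed,
    }
    return g, labels, truth


def fixture_small() -> tuple[GenotypeMatrix, CaseControlLabels]:
    """Deterministic 60-individual, 12-SNP toy cohort.

    Nine background SNPs plus one planted MAF-0.5 parity triplet
    (rstrip0_0..rstrip0_2); fixed seed, no missing calls.  Used across the
    test suite wherever a tiny but structurally complete cohort is needed.
    """
    spec = SimulationSpec(
        n_cases=30,
        n_controls=30,
        n_background_snps=9,
        planted_triplets=[make_parity_penetrance(base=0.1, effect=0.08)],
        baseline_prevalence=0.1,
        missing_rate=0.0,
        seed=20240917,
    )
    g, labels, _truth = simulate_cohort(spec)
    return g, labels
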