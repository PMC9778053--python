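"""Synthetic genotype/phenotype generator for genomic-selection experiments.

The generator draws independent biallelic markers under Hardy-Weinberg
equilibrium with per-marker minor allele frequencies (MAF) uniform on
[0.1, 0.5], then builds phenotypes from the mixed linear model

    y = mu * 1 + Z_qtn @ effects + u + eps,

where ``u ~ MVN(0, sigma_g^2 K)`` is a polygenic background term tied to the
realized genomic relationship matrix K and ``eps ~ N(0, sigma_e^2 I)``.

Two quantitative-trait-nucleotide (QTN) architectures are supported:

* a single QTN at a fixed marker position (default: marker 98) explaining a
  target heritability (default 0.1), and
* ``n_qtn`` randomly placed QTNs restricted to common markers (MAF > 0.3)
  jointly explaining a target proportion of phenotypic variance (default 0.5).

Heritability convention: a component with target share ``h2`` of phenotypic
variance gets variance ``h2 / (1 - h2) * (sigma_g^2 + sigma_e^2)``.  The
polygenic level is parameterized as a multiple of the residual variance,
``sigma_g^2 = background_multiplier * sigma_e^2``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError

__all__ = [
    "GenotypeMatrix",
    "SimulationScenario",
    "SimulatedDataset",
    "simulate_genotypes",
    "make_scenario_one_qtn",
    "make_scenario_multi_qtn",
    "simulate_phenotype",
]

DEFAULT_MU = 10.0
DEFAULT_SIGMA2_E = 10.0


@dataclass(frozen=True)
class GenotypeMatrix:
    """An n x q allele-dosage matrix with marker metadata.

    ``dosages`` holds counts of the alternate allele in {0, 1, 2} (stored as
    float64 so downstream linear algebra never copies). ``maf`` is the folded
    (minor) allele frequency computed from each column.
    """

    dosages: np.ndarray
    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=np.float64)
        if d.ndim != 2:
            raise DataError(f"dosage matrix must be 2-D, got shape {d.shape}")
        n, q = d.shape
        if n < 2 or q < 1:
            raise DataError(f"need n >= 2 individuals and q >= 1 markers, got {n} x {q}")
        if not np.isin(d, (0.0, 1.0, 2.0)).all():
            raise DataError("dosages must all be in {0, 1, 2}")
        if len(self.marker_ids) != q:
            raise DataError(f"{len(self.marker_ids)} marker ids for {q} markers")
        object.__setattr__(self, "dosages", d)
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def q(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency p_k per marker (unfolded)."""
        return self.dosages.mean(axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth genetic architecture plus variance settings.

    ``qtn_indices`` are 1-based marker positions; ``qtn_effects`` the additive
    allele-substitution effects. ``background_multiplier`` m sets the polygenic
    variance sigma_g^2 = m * sigma2_e.
    """

    n: int
    q: int
    qtn_indices: tuple[int, ...]
    qtn_effects: tuple[float, ...]
    mu: float = DEFAULT_MU
    sigma2_e: float = DEFAULT_SIGMA2_E
    background_multiplier: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.qtn_indices)
        if len(set(idx)) != len(idx):
            raise DataError("QTN indices must be distinct")
        if idx and (min(idx) < 1 or max(idx) > self.q):
            raise DataError(f"QTN indices must lie in [1, {self.q}]")
        if len(idx) != len(self.qtn_effects):
            raise DataError("qtn_indices and qtn_effects length mismatch")
        if self.sigma2_e <= 0:
            raise DataError("sigma2_e must be positive")
        if self.background_multiplier < 0:
            raise DataError("background_multiplier must be >= 0")
        object.__setattr__(self, "qtn_indices", idx)
        object.__setattr__(self, "qtn_effects", tuple(float(a) for a in self.qtn_effects))

    @property
    def sigma2_g(self) -> float:
        return self.background_multiplier * self.sigma2_e

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SimulatedDataset:
    """A realized phenotype with its stored truth components.

    Invariant: ``phenotype == truth.mu + genetic + polygenic + residual``
    exactly (same floating point additions, no re-randomization).
    """

    genotypes: GenotypeMatrix
    phenotype: np.ndarray
    genetic: np.ndarray
    polygenic: np.ndarray
    residual: np.ndarray
    truth: SimulationScenario


def _validate_maf_bounds(maf_low: float, maf_high: float) -> None:
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise DataError(
            f"MAF bounds must satisfy 0 < low <= high <= 0.5, got [{maf_low}, {maf_high}]"
        )


def simulate_genotypes(
    n: int,
    q: int,
    maf_low: float = 0.1,
    maf_high: float = 0.5,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Draw an n x q HWE genotype matrix with MAF ~ U[maf_low, maf_high].

    Each marker k gets an allele frequency p_k uniform on the interval, then n
    dosages Binomial(2, p_k), i.e. HWE proportions p^2 : 2p(1-p) : (1-p)^2.
    Markers are mutually independent. Columns that come out monomorphic are
    redrawn (with a fresh frequency) so every marker is polymorphic in-sample.
    """
    _validate_maf_bounds(maf_low, maf_high)
    if n < 2 or q < 1:
        raise DataError(f"need n >= 2 and q >= 1, got n={n}, q={q}")
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=q)
    g = rng.binomial(2, p, size=(n, q)).astype(np.float64)
    # resample degenerate (constant) columns until polymorphic
    for _ in range(1000):
        col_min = g.min(axis=0)
        bad = np.flatnonzero(col_min == g.max(axis=0))
        if bad.size == 0:
            break
        p_bad = rng.uniform(maf_low, maf_high, size=bad.size)
        g[:, bad] = rng.binomial(2, p_bad, size=(n, bad.size))
    else:  # pragma: no cover - astronomically unlikely for valid bounds
        raise DataError("could not draw polymorphic markers; widen MAF bounds or raise n")
    ids = tuple(f"m{k + 1}" for k in range(q))
    return GenotypeMatrix(dosages=g, marker_ids=ids)


def _component_variance(h2: float, sigma2_g: float, sigma2_e: float) -> float:
    # variance v with v / (v + sigma2_g + sigma2_e) = h2
    return h2 / (1.0 - h2) * (sigma2_g + sigma2_e)


def make_scenario_one_qtn(
    genotypes: GenotypeMatrix,
    background_multiplier: float,
    seed: int,
    h2: float = 0.1,
    qtn_index: int = 98,
    mu: float = DEFAULT_MU,
    sigma2_e: float = DEFAULT_SIGMA2_E,
) -> SimulationScenario:
    """Single fixed-position QTN (default marker 98) with target heritability.

    The additive effect a solves ``a^2 * 2 p (1-p) = h2/(1-h2) * (sigma_g^2 +
    sigma_e^2)`` with p the realized allele frequency at the QTN marker, so the
    QTN's expected share of phenotypic variance equals ``h2``.
    """
    if genotypes.q < qtn_index:
        raise DataError(f"need at least {qtn_index} markers, got q={genotypes.q}")
    if not 0.0 < h2 < 1.0:
        raise DataError("h2 must lie in (0, 1)")
    sigma2_g = background_multiplier * sigma2_e
    v_qtn = _component_variance(h2, sigma2_g, sigma2_e)
    p = genotypes.allele_freq[qtn_index - 1]
    effect = float(np.sqrt(v_qtn / (2.0 * p * (1.0 - p))))
    return SimulationScenario(
        n=genotypes.n,
        q=genotypes.q,
        qtn_indices=(qtn_index,),
        qtn_effects=(effect,),
        mu=mu,
        sigma2_e=sigma2_e,
        background_multiplier=background_multiplier,
        seed=seed,
    )


def make_scenario_multi_qtn(
    genotypes: GenotypeMatrix,
    background_multiplier: float,
    seed: int,
    n_qtn: int = 50,
    total_pve: float = 0.5,
    maf_min: float = 0.3,
    mu: float = DEFAULT_MU,
    sigma2_e: float = DEFAULT_SIGMA2_E,
) -> SimulationScenario:
    """``n_qtn`` random QTNs at common markers with a total variance share.

    QTN positions are sampled uniformly without replacement among markers with
    MAF > ``maf_min``. The total genetic variance implied by ``total_pve`` is
    split equally across QTNs; each effect magnitude is solved from the
    marker's realized allele frequency, with an independent random sign.
    """
    if not 0.0 < total_pve < 1.0:
        raise DataError("total_pve must lie in (0, 1)")
    eligible = np.flatnonzero(genotypes.maf > maf_min)
    if eligible.size < n_qtn:
        raise DataError(
            f"only {eligible.size} markers with MAF > {maf_min}; need {n_qtn}"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(eligible, size=n_qtn, replace=False))
    sigma2_g = background_multiplier * sigma2_e
    v_total = _component_variance(total_pve, sigma2_g, sigma2_e)
    v_each = v_total / n_qtn
    p = genotypes.allele_freq[chosen]
    mag = np.sqrt(v_each / (2.0 * p * (1.0 - p)))
    signs = rng.choice((-1.0, 1.0), size=n_qtn)
    return SimulationScenario(
        n=genotypes.n,
        q=genotypes.q,
        qtn_indices=tuple(int(i) + 1 for i in chosen),
        qtn_effects=tuple(signs * mag),
        mu=mu,
        sigma2_e=sigma2_e,
        background_multiplier=background_multiplier,
        seed=seed,
    )


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    scenario: SimulationScenario,
    kinship=None,
) -> SimulatedDataset:
    """Realize a phenotype vector from a scenario.

    ``u`` is drawn from MVN(0, sigma_g^2 K) via a (jittered) Cholesky factor of
    the kinship matrix; when ``background_multiplier == 0`` the polygenic term
    is exactly the zero vector and no kinship is required. The residual is iid
    N(0, sigma2_e). All randomness derives from ``scenario.seed``.
    """
    if genotypes.n != scenario.n or genotypes.q != scenario.q:
        raise DataError(
            f"genotypes are {genotypes.n} x {genotypes.q}, scenario expects "
            f"{scenario.n} x {scenario.q}"
        )
    n = genotypes.n
    # child streams: one for u, one for eps, decoupled from scenario sampling
    ss_u, ss_e = np.random.SeedSequence(scenario.seed).spawn(2)
    if scenario.sigma2_g > 0:
        if kinship is None:
            raise DataError("kinship matrix required when background_multiplier > 0")
        K = np.asarray(kinship.values if hasattr(kinship, "values") else kinship, float)
        if K.shape != (n, n):
            raise DataError(f"kinship is {K.shape}, expected ({n}, {n})")
        jitter = 1e-8 * max(np.trace(K) / n, 1.0)
        try:
            L = np.linalg.cholesky(K + jitter * np.eye(n))
        except np.linalg.LinAlgError as err:
            raise DataError("kinship matrix is not positive semi-definite") from err
        u = np.sqrt(scenario.sigma2_g) * (
            L @ np.random.default_rng(ss_u).standard_normal(n)
        )
    else:
        u = np.zeros(n)
    eps = np.sqrt(scenario.sigma2_e) * np.random.default_rng(ss_e).standard_normal(n)
    idx = np.asarray(scenario.qtn_indices, dtype=int) - 1
    genetic = genotypes.dosages[:, idx] @ np.asarray(scenario.qtn_effects)
    y = scenario.mu + genetic + u + eps
    return SimulatedDataset(
        genotypes=genotypes,
        phenotype=y,
        genetic=genetic,
        polygenic=u,
        residual=eps,
        truth=scenario,
    )
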