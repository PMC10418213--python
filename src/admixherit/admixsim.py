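"""Forward-in-time simulation of admixed cohorts with unlinked loci.

Two demographic models are supported.  Hybrid isolation (HI): the two
source populations mix once in proportions p : 1-p and there is no further
gene flow, so E(theta) stays at p while V(theta) decays by (1+P)/2 per
generation.  Continuous gene flow (CGF): population B receives a constant
migrant fraction q = 1-(1-p)^(1/T) from population A every generation, so
that after T generations the mean ancestry equals p.

Ancestry-assortative mating is controlled by P, the Pearson correlation of
partner ancestries across couples, achieved by a hill-climbing partner-swap
search (the tolerance starts at 0.01 and is relaxed stepwise to 0.04 when
V(theta) is too small to hit the target, mirroring the difficulty of
finding mates late in time; if even that fails the cohort is flagged and
pairing falls back to random).

Reproduction is Mendelian over unlinked loci: each offspring allele's
ancestry is Bernoulli in the corresponding parent's global ancestry, and
its allelic state is Bernoulli(fA) or Bernoulli(fB) conditional on that
ancestry.  Individual ancestry theta is always the mean of the
local-ancestry dosages over 2m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import ArchitectureSpec

__all__ = [
    "SimulationConfig",
    "AdmixedCohort",
    "TraitRealization",
    "found_population",
    "mate_pairs",
    "reproduce",
    "migrate",
    "simulate_admixture",
    "genetic_values",
    "simulate_phenotype",
    "ancestry_moments",
]


@dataclass
class SimulationConfig:
    """Parameters of an admixture simulation."""

    model: str  # "hi" or "cgf"
    p: float  # target overall ancestry proportion from population A
    P: float = 0.0  # assortative-mating ancestry correlation
    T: int = 10  # generations simulated after founding
    n: int = 1000  # individuals per generation
    tol: float = 0.01  # mating-correlation tolerance (relaxed up to 0.04)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.model = self.model.lower()
        if self.model not in ("hi", "cgf"):
            raise ValueError("model must be 'hi' or 'cgf'")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie in (0, 1)")
        if not 0.0 <= self.P < 1.0:
            raise ValueError("P must lie in [0, 1)")
        if self.n % 2:
            raise ValueError("n must be even (mating requires couples)")
        if self.T < 0:
            raise ValueError("T must be >= 0")

    @property
    def q(self) -> float:
        """Per-generation migrant fraction (CGF); 0 under HI."""
        if self.model == "hi":
            return 0.0
        if self.T < 1:
            raise ValueError("CGF needs T >= 1")
        return 1.0 - (1.0 - self.p) ** (1.0 / self.T)


@dataclass
class AdmixedCohort:
    """One generation: ancestries, local ancestry and genotype dosages."""

    t: int
    theta: np.ndarray  # (n,) individual ancestry fractions
    gamma: np.ndarray  # (n, m) local-ancestry dosages in {0,1,2}
    X: np.ndarray  # (n, m) genotype dosages in {0,1,2}
    pairing: np.ndarray | None = None  # (n/2, 2) couples used to produce this cohort
    mating_flagged: bool = False  # True if the pairing search fell back to random
    realized_P: float = np.nan  # realized mate-ancestry correlation of `pairing`

    @property
    def n(self) -> int:
        return self.theta.size

    @property
    def m(self) -> int:
        return self.gamma.shape[1]


@dataclass
class TraitRealization:
    """Phenotypes y = g + e at a target heritability."""

    g: np.ndarray
    y: np.ndarray
    h2: float
    sigma_e2: float


def _draw_genotypes_given_gamma(
    gamma_alleles: tuple[np.ndarray, np.ndarray],
    arch: ArchitectureSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotype dosage matrix given per-allele ancestry indicator matrices."""
    fA, fB = arch.freqs.fA, arch.freqs.fB
    X = np.zeros(gamma_alleles[0].shape, dtype=np.int8)
    for anc in gamma_alleles:
        f = np.where(anc, fA[None, :], fB[None, :])
        X += (rng.random(anc.shape) < f).astype(np.int8)
    return X


def found_population(
    cfg: SimulationConfig,
    arch: ArchitectureSpec,
    rng: np.random.Generator | None = None,
) -> AdmixedCohort:
    """Generation-0 cohort.

    HI: each individual is an unadmixed population-A member with
    probability p (theta=1, gamma all 2) else population B.  CGF: all
    residents are population B; migration starts in the first loop pass.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    n, m = cfg.n, arch.m
    if cfg.model == "hi":
        from_a = rng.random(n) < cfg.p
    else:
        from_a = np.zeros(n, dtype=bool)
    anc = np.broadcast_to(from_a[:, None], (n, m))
    gamma = (2 * anc).astype(np.int8)
    X = _draw_genotypes_given_gamma((anc, anc), arch, rng)
    theta = gamma.mean(axis=1) / 2.0
    return AdmixedCohort(t=0, theta=theta, gamma=gamma, X=X)


def _pair_correlation(theta: np.ndarray, pairs: np.ndarray) -> float:
    a = theta[pairs[:, 0]]
    b = theta[pairs[:, 1]]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def mate_pairs(
    theta: np.ndarray,
    P: float,
    tol: float = 0.01,
    max_iter: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, float, bool]:
    """Pair individuals so partner ancestries correlate at ~P.

    Starts from an ancestry-sorted pairing when P > 0 (adjacent ranks give
    near-maximal correlation) or a random pairing when P = 0, then
    hill-climbs by random partner swaps that reduce |corr - P|.  The
    tolerance is relaxed 0.01 -> 0.02 -> 0.04 if the target is
    unattainable; if the relaxed tolerance still fails (e.g. V(theta)=0
    makes the correlation undefined) a random pairing is returned with
    ``flagged=True``.

    Returns (pairs, realized_correlation, flagged) where pairs is an
    (n/2, 2) index array of disjoint couples.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    if n % 2:
        raise ValueError("need an even number of individuals")
    half = n // 2

    def random_pairs() -> np.ndarray:
        perm = rng.permutation(n)
        return perm.reshape(half, 2)

    if np.std(theta) == 0:
        return random_pairs(), np.nan, True

    if P > 0:
        order = np.argsort(theta, kind="stable")
        pairs = order.reshape(half, 2).copy()
        # shuffle couple order and role so the start is not pathological
        rng.shuffle(pairs, axis=0)
    else:
        pairs = random_pairs()

    a = theta[pairs[:, 0]].copy()
    b = theta[pairs[:, 1]].copy()

    # incremental sufficient statistics for the Pearson correlation
    sa, sb = a.sum(), b.sum()
    saa, sbb, sab = a @ a, b @ b, a @ b

    def corr() -> float:
        va = saa - sa * sa / half
        vb = sbb - sb * sb / half
        if va <= 0 or vb <= 0:
            return np.nan
        return (sab - sa * sb / half) / np.sqrt(va * vb)

    c = corr()
    best = abs(c - P)
    it = 0
    while best > tol and it < max_iter:
        it += 1
        i, j = rng.integers(0, half, size=2)
        if i == j:
            continue
        # swap partners: (a_i,b_i),(a_j,b_j) -> (a_i,b_j),(a_j,b_i)
        d_sab = a[i] * b[j] + a[j] * b[i] - a[i] * b[i] - a[j] * b[j]
        new_sab = sab + d_sab
        va = saa - sa * sa / half
        vb = sbb - sb * sb / half
        new_c = (new_sab - sa * sb / half) / np.sqrt(va * vb)
        if abs(new_c - P) < best:
            sab = new_sab
            b[i], b[j] = b[j], b[i]
            pairs[[i, j], 1] = pairs[[j, i], 1]
            c = new_c
            best = abs(c - P)
    for relaxed in (tol, 2 * tol, 4 * tol):
        if best <= relaxed:
            return pairs, c, False
    fallback = random_pairs()
    return fallback, _pair_correlation(theta, fallback), True


def reproduce(
    pairing: np.ndarray,
    parents: AdmixedCohort,
    arch: ArchitectureSpec,
    n_offspring: int,
    rng: np.random.Generator | int | None = None,
) -> AdmixedCohort:
    """Produce the next generation from mated couples.

    Each offspring draws a couple uniformly with replacement.  At every
    locus the maternal allele's ancestry is Bernoulli(theta_mother) and
    the paternal one Bernoulli(theta_father); allelic states follow
    Bernoulli(fA or fB) given the ancestry.  Offspring theta is recomputed
    from gamma.
    """
    if pairing is None or len(pairing) == 0:
        raise ValueError("empty pairing")
    rng = np.random.default_rng(rng)
    m = arch.m
    fam = rng.integers(0, len(pairing), size=n_offspring)
    th_m = parents.theta[pairing[fam, 0]]
    th_f = parents.theta[pairing[fam, 1]]
    anc_m = rng.random((n_offspring, m)) < th_m[:, None]
    anc_f = rng.random((n_offspring, m)) < th_f[:, None]
    gamma = anc_m.astype(np.int8) + anc_f.astype(np.int8)
    X = _draw_genotypes_given_gamma((anc_m, anc_f), arch, rng)
    theta = gamma.mean(axis=1) / 2.0
    return AdmixedCohort(
        t=parents.t + 1, theta=theta, gamma=gamma, X=X, pairing=np.asarray(pairing)
    )


def migrate(
    cohort: AdmixedCohort,
    cfg: SimulationConfig,
    arch: ArchitectureSpec,
    rng: np.random.Generator | int | None = None,
) -> AdmixedCohort:
    """Replace a fraction q of the cohort with unadmixed population-A migrants."""
    if cfg.model != "cgf":
        raise ValueError("migration applies to the CGF model only")
    rng = np.random.default_rng(rng)
    n, m = cohort.n, cohort.m
    n_mig = int(round(cfg.q * n))
    if n_mig == 0:
        return cohort
    idx = rng.choice(n, size=n_mig, replace=False)
    theta = cohort.theta.copy()
    gamma = cohort.gamma.copy()
    X = cohort.X.copy()
    theta[idx] = 1.0
    gamma[idx] = 2
    anc = np.ones((n_mig, m), dtype=bool)
    X[idx] = _draw_genotypes_given_gamma((anc, anc), arch, rng)
    return AdmixedCohort(
        t=cohort.t, theta=theta, gamma=gamma, X=X,
        pairing=cohort.pairing, mating_flagged=cohort.mating_flagged,
        realized_P=cohort.realized_P,
    )


def simulate_admixture(
    cfg: SimulationConfig,
    arch: ArchitectureSpec,
    keep: str = "all",
) -> list[AdmixedCohort]:
    """Run the generation loop: [migrate (CGF)] -> mate -> reproduce.

    Returns the trajectory of cohorts from generation 0 to T.  With
    ``keep="last"`` only the final cohort is returned (in a length-1
    list) to bound memory for long runs.
    """
    root = np.random.SeedSequence(cfg.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(cfg.T + 1)]
    cohort = found_population(cfg, arch, rng=streams[0])
    out = [cohort]
    for t in range(1, cfg.T + 1):
        rng = streams[t]
        current = cohort
        if cfg.model == "cgf":
            current = migrate(current, cfg, arch, rng=rng)
        pairs, realized, flagged = mate_pairs(
            current.theta, cfg.P, tol=cfg.tol, seed=rng
        )
        cohort = reproduce(pairs, current, arch, cfg.n, rng=rng)
        cohort.mating_flagged = flagged
        cohort.realized_P = realized
        if keep == "all":
            out.append(cohort)
        else:
            out = [cohort]
    return out


def genetic_values(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Genetic values g = X beta."""
    X = np.asarray(X)
    beta = np.asarray(beta, dtype=float)
    if X.shape[1] != beta.size:
        raise ValueError("X and beta shapes do not conform")
    return X @ beta


def simulate_phenotype(
    g: np.ndarray, h2: float, seed: int | np.random.Generator | None = None
) -> TraitRealization:
    """Add environmental noise so the trait has heritability h2.

    e ~ N(0, V(g)(1-h2)/h2) with V(g) the population variance of g.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    g = np.asarray(g, dtype=float)
    vg = float(np.var(g))
    if h2 < 1.0 and vg == 0.0:
        raise ValueError("V(g)=0: cannot scale environmental noise")
    sigma_e2 = vg * (1.0 - h2) / h2
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=g.size) if sigma_e2 > 0 else 0.0
    return TraitRealization(g=g, y=g + e, h2=h2, sigma_e2=sigma_e2)


def ancestry_moments(cohort: AdmixedCohort) -> tuple[float, float]:
    """Sample mean and (population) variance of individual ancestry."""
    if cohort.n < 2:
        raise ValueError("need at least two individuals")
    return float(cohort.theta.mean()), float(np.var(cohort.theta))
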