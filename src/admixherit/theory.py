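"""Closed-form variance decompositions for admixed populations.

For a trait with effects beta and source-population frequencies fA, fB, the
genetic variance in an admixed population with individual-ancestry moments
E(theta), V(theta) decomposes into four terms:

  term 1: 2 E(th) sum b^2 fA(1-fA) + 2 (1-E(th)) sum b^2 fB(1-fB)
  term 2: 2 E(th)(1-E(th)) sum b^2 (fA-fB)^2
  term 3: 2 V(th) sum b^2 (fA-fB)^2
  term 4: 4 V(th) sum_{i!=j} b_i b_j (f_iA-f_iB)(f_jA-f_jB)

Terms 1-3 are the genic variance (per-locus contributions); term 4 is the
directional-LD (cross-locus covariance) contribution induced by ancestry
variation, positive under divergent and negative under stabilizing
architectures.  The same decomposition with local-ancestry effects
phi_i = beta_i (f_iA - f_iB) gives the variance explained by local
ancestry, V_gamma = term2 + term3 + term4.

The estimand table records what each (GRM scaling x ancestry adjustment)
combination of a random-effects heritability estimator measures:
standard scaling -> term1+term2; variance scaling -> term1+term2+term3;
LD scaling -> the full total; any scaling with individual ancestry as a
fixed effect -> term1+term2-term3 (the expected variance conditional on
ancestry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import ArchitectureSpec

__all__ = [
    "VarianceDecomposition",
    "variance_components",
    "local_ancestry_components",
    "estimand_table",
    "expected_ancestry_moments",
    "he_estimand_decomposition",
    "simulated_variance_oracle",
]


@dataclass
class VarianceDecomposition:
    """The four variance terms plus the moments they were evaluated at."""

    term_1_1: float
    term_1_2: float
    term_1_3: float
    term_1_4: float
    Etheta: float
    Vtheta: float
    flavor: str = "genotype"  # or "local_ancestry"

    @property
    def genic(self) -> float:
        return self.term_1_1 + self.term_1_2 + self.term_1_3

    @property
    def ld_contribution(self) -> float:
        return self.term_1_4

    @property
    def total(self) -> float:
        return self.term_1_1 + self.term_1_2 + self.term_1_3 + self.term_1_4

    def as_dict(self) -> dict:
        return {
            "term_1_1": self.term_1_1,
            "term_1_2": self.term_1_2,
            "term_1_3": self.term_1_3,
            "term_1_4": self.term_1_4,
            "genic": self.genic,
            "ld_contribution": self.ld_contribution,
            "total": self.total,
            "Etheta": self.Etheta,
            "Vtheta": self.Vtheta,
            "flavor": self.flavor,
        }


def _check_moments(Etheta: float, Vtheta: float) -> None:
    if not 0.0 <= Etheta <= 1.0:
        raise ValueError("Etheta must lie in [0, 1]")
    if Vtheta < 0.0 or Vtheta > Etheta * (1.0 - Etheta) + 1e-12:
        raise ValueError(
            f"impossible ancestry moments: V(theta)={Vtheta} exceeds "
            f"E(theta)(1-E(theta))={Etheta * (1 - Etheta)}"
        )


def variance_components(
    arch: ArchitectureSpec, Etheta: float, Vtheta: float
) -> VarianceDecomposition:
    """Four-term decomposition of the genetic variance V(g)."""
    _check_moments(Etheta, Vtheta)
    beta = arch.beta
    fA, fB = arch.freqs.fA, arch.freqs.fB
    delta = fA - fB
    b2d2 = float(beta**2 @ delta**2)
    bd = beta * delta
    cross = float(bd.sum() ** 2 - bd @ bd)  # sum_{i != j} b_i b_j d_i d_j
    t1 = 2.0 * Etheta * float(beta**2 @ (fA * (1 - fA))) + 2.0 * (
        1.0 - Etheta
    ) * float(beta**2 @ (fB * (1 - fB)))
    t2 = 2.0 * Etheta * (1.0 - Etheta) * b2d2
    t3 = 2.0 * Vtheta * b2d2
    t4 = 4.0 * Vtheta * cross
    return VarianceDecomposition(t1, t2, t3, t4, Etheta, Vtheta, flavor="genotype")


def local_ancestry_components(
    arch: ArchitectureSpec, Etheta: float, Vtheta: float
) -> VarianceDecomposition:
    """Decomposition of the variance explained by local ancestry, V_gamma.

    With phi_i = beta_i (f_iA - f_iB):
      V_gamma = 2 E(th)(1-E(th)) sum phi^2 + 2 V(th) sum phi^2
                + 4 V(th) sum_{i != j} phi_i phi_j
    which equals term2 + term3 + term4 of the genotype-flavor
    decomposition; the within-ancestry genic piece (term 1) is zero.
    """
    _check_moments(Etheta, Vtheta)
    phi = arch.phi
    p2 = float(phi @ phi)
    cross = float(phi.sum() ** 2 - p2)
    t2 = 2.0 * Etheta * (1.0 - Etheta) * p2
    t3 = 2.0 * Vtheta * p2
    t4 = 4.0 * Vtheta * cross
    return VarianceDecomposition(0.0, t2, t3, t4, Etheta, Vtheta, flavor="local_ancestry")


def estimand_table(decomp: VarianceDecomposition) -> dict[tuple[str, bool], float]:
    """Expected estimate per (GRM scaling, ancestry-adjusted) cell.

    Keys are (scaling, adjusted) with scaling in {standard, variance, ld}
    and adjusted a bool.  All adjusted cells share the conditional-variance
    estimand term1+term2-term3.
    """
    if decomp.flavor != "genotype":
        raise ValueError("estimand table is defined for the genotype flavor")
    unadj = {
        "standard": decomp.term_1_1 + decomp.term_1_2,
        "variance": decomp.term_1_1 + decomp.term_1_2 + decomp.term_1_3,
        "ld": decomp.total,
    }
    adj = decomp.term_1_1 + decomp.term_1_2 - decomp.term_1_3
    table: dict[tuple[str, bool], float] = {}
    for scaling, value in unadj.items():
        table[(scaling, False)] = value
        table[(scaling, True)] = adj
    return table


def expected_ancestry_moments(
    model: str,
    p: float,
    P: float,
    T: int,
    n_loci: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-generation expected (E(theta_t), V(theta_t)) for t = 0..T.

    HI: E constant at p; V_0 = p(1-p) and V_t = V_{t-1} (1+P)/2.
    CGF: founding cohort is unadmixed population B; with per-generation
    migrant fraction q = 1-(1-p)^(1/T),
      E_t = q + (1-q) E_{t-1}
      V_t = (1+P)/2 [ q(1-q)(1 - E_{t-1})^2 + (1-q) V_{t-1} ]
    (migration, then assortative mating with ancestry correlation P, then
    reproduction; the generation-t cohort is the offspring).

    If ``n_loci`` is given, the finite-locus segregation variance
    (E'(1-E') - V')/(2 n_loci) added by Mendelian sampling over unlinked
    loci is included each generation; the default reproduces the
    continuous-ancestry recursion.
    """
    if model not in ("hi", "cgf"):
        raise ValueError("model must be 'hi' or 'cgf'")
    E = np.empty(T + 1)
    V = np.empty(T + 1)
    if model == "hi":
        E[:] = p
        V[0] = p * (1.0 - p)
        q = 0.0
    else:
        if T < 1:
            raise ValueError("CGF needs T >= 1")
        q = 1.0 - (1.0 - p) ** (1.0 / T)
        E[0] = 0.0
        V[0] = 0.0
    for t in range(1, T + 1):
        if model == "hi":
            Epost, Vpost = E[t - 1], V[t - 1]
        else:
            Epost = q + (1.0 - q) * E[t - 1]
            Vpost = (1.0 - q) * V[t - 1] + q * (1.0 - q) * (1.0 - E[t - 1]) ** 2
            E[t] = Epost
        V[t] = Vpost * (1.0 + P) / 2.0
        if n_loci is not None:
            V[t] += (Epost * (1.0 - Epost) - Vpost) / (2.0 * n_loci)
    return E, V


def he_estimand_decomposition(
    u: np.ndarray, Z: np.ndarray
) -> tuple[float, float]:
    """Split the HE-regression slope for g = Z u into genic and LD parts.

    Z is the column-centered scaled genotype matrix, u the corresponding
    scaled-genotype effects.  With psi = Z Z'/m the GRM and
    Y_kl = g_k g_l the phenotypic cross-products, the HE slope
    Cov(Y, psi)/Var(psi) over the off-diagonal pairs splits linearly into

      genic = Cov(sum_i u_i^2 z_ik z_il, psi) / Var(psi)
      ld    = Cov(sum_{i != j} u_i u_j z_ik z_jl, psi) / Var(psi)

    whose sum equals the slope exactly.  In the absence of directional LD
    the second term is zero in expectation.  All ordered pairs are used;
    intended as an oracle at n <= a few thousand.
    """
    Z = np.asarray(Z, dtype=float)
    u = np.asarray(u, dtype=float)
    n, m = Z.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    if np.max(np.abs(Z.mean(axis=0))) > 1e-8:
        raise ValueError("Z columns must be centered")
    K = Z @ Z.T / m
    g = Z @ u
    Y = np.outer(g, g)
    Kdiag = Z * (u**2) @ Z.T  # sum_i u_i^2 z_ik z_il
    Yoff = Y - Kdiag  # sum_{i != j} u_i u_j z_ik z_jl
    iu = np.triu_indices(n, k=1)
    psi = K[iu]
    vp = np.var(psi)
    if vp == 0:
        raise ValueError("GRM off-diagonals are constant; slope undefined")
    genic = float(np.cov(Kdiag[iu], psi, bias=True)[0, 1] / vp)
    ld = float(np.cov(Yoff[iu], psi, bias=True)[0, 1] / vp)
    return genic, ld


def simulated_variance_oracle(
    arch: ArchitectureSpec,
    Etheta: float,
    Vtheta: float,
    n: int = 200_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Brute-force Monte-Carlo V(g) at given ancestry moments.

    Draws individual ancestries theta from a Beta distribution matched to
    (Etheta, Vtheta) (degenerate at Etheta when Vtheta=0), local ancestry
    gamma_i ~ Bin(2, theta) independently per locus, and genotype alleles
    Bernoulli(fA) or Bernoulli(fB) conditional on each allele's ancestry.
    Returns (V(g) estimate, its Monte-Carlo standard error).  Independent
    of the closed-form path; used to validate it.
    """
    rng = np.random.default_rng(seed)
    if Vtheta == 0.0:
        theta = np.full(n, Etheta)
    else:
        c = Etheta * (1.0 - Etheta) / Vtheta - 1.0
        if c <= 0:
            raise ValueError("V(theta) too large for a Beta ancestry law")
        theta = rng.beta(Etheta * c, (1.0 - Etheta) * c, size=n)
    m = arch.m
    g = np.zeros(n)
    # per-allele draws, vectorized over individuals locus by locus to bound memory
    fA, fB, beta = arch.freqs.fA, arch.freqs.fB, arch.beta
    for i in range(m):
        anc1 = rng.random(n) < theta
        anc2 = rng.random(n) < theta
        f1 = np.where(anc1, fA[i], fB[i])
        f2 = np.where(anc2, fA[i], fB[i])
        x = (rng.random(n) < f1).astype(float) + (rng.random(n) < f2)
        g += beta[i] * x
    gc = g - g.mean()
    v = float(gc @ gc / n)
    mu4 = float((gc**4).mean())
    se = float(np.sqrt(max(mu4 - v**2, 0.0) / n))
    return v, se
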