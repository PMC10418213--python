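"""Two-source-population genetic architectures.

An architecture is the pair (allele frequencies in source populations A and
B, signed per-locus effects).  Frequencies are drawn under the
Balding-Nichols model: both derived populations draw their frequency at a
locus from Beta(f0(1-F)/F, (1-f0)(1-F)/F) around a shared ancestral
frequency f0, where F is the divergence (inbreeding) coefficient.  Effect
magnitudes are fixed at beta_i = 1/sqrt(2 m fbar_i (1 - fbar_i)) so that
every locus contributes 1/m to the genic variance at the mean frequency and
the total sums to one; only the *signs* of the effects distinguish traits.

Sign configurations are selected by permutation: among random sign vectors
we keep the one maximizing or minimizing either the directional-LD
contribution (the cross-locus term of the variance decomposition) or the
between-population genetic variance Vgb.  Maximizing mimics divergent
selection (trait-increasing alleles systematically more frequent in one
population), minimizing mimics stabilizing selection (compensating
frequency differences).  The marginal per-locus quantities (FST, genic
variance) are untouched by sign choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SourceFrequencies",
    "ArchitectureSpec",
    "draw_source_frequencies",
    "assign_effect_magnitudes",
    "permute_signs_select",
    "between_population_variance",
    "read_architecture",
    "write_architecture",
]

#: default retention bounds for derived-population allele frequencies
DEFAULT_MAF_BOUNDS = (0.01, 0.99)
#: rejection-sampling budget per locus
MAX_REJECTION_ATTEMPTS = 100_000


@dataclass
class SourceFrequencies:
    """Allele frequencies of m biallelic loci in two diverged populations.

    Attributes
    ----------
    f0 : ndarray
        Ancestral allele frequencies.
    fA, fB : ndarray
        Frequencies in derived populations A and B.
    F : float
        Balding-Nichols divergence coefficient used for the draw.
    """

    f0: np.ndarray
    fA: np.ndarray
    fB: np.ndarray
    F: float

    def __post_init__(self) -> None:
        self.f0 = np.asarray(self.f0, dtype=float)
        self.fA = np.asarray(self.fA, dtype=float)
        self.fB = np.asarray(self.fB, dtype=float)
        if not (self.f0.shape == self.fA.shape == self.fB.shape):
            raise ValueError("f0, fA, fB must have identical length")
        if self.m == 0:
            raise ValueError("need at least one locus")
        for arr, name in ((self.f0, "f0"), (self.fA, "fA"), (self.fB, "fB")):
            if np.any((arr <= 0) | (arr >= 1)):
                raise ValueError(f"{name} must lie strictly in (0, 1)")

    @property
    def m(self) -> int:
        return self.f0.size

    @property
    def fbar(self) -> np.ndarray:
        """Mean frequency (fA + fB)/2 per locus."""
        return (self.fA + self.fB) / 2.0

    def per_locus_fst(self, estimator: str = "ancestral") -> np.ndarray:
        """Per-locus differentiation between the two derived populations.

        estimator:
          * ``"ancestral"`` -- variance of (fA, fB) around the known
            ancestral f0, over f0(1-f0).  Expectation is exactly F under
            the Balding-Nichols model; this is the generator-side notion
            of per-locus FST.
          * ``"hudson"`` -- 1 - Hw/Hb with Hw the mean within-population
            heterozygosity and Hb the between-population heterozygosity.
          * ``"nei"`` -- GST-style V(f)/(fbar(1-fbar)) with
            V(f) = (fA-fB)^2/4 over the two populations.
          * ``"plain"`` -- (fA-fB)^2 / (2 fbar (1-fbar)).
        """
        fA, fB, f0 = self.fA, self.fB, self.f0
        if estimator == "ancestral":
            return ((fA - f0) ** 2 + (fB - f0) ** 2) / (2.0 * f0 * (1.0 - f0))
        if estimator == "hudson":
            hb = fA * (1 - fB) + fB * (1 - fA)
            hw = fA * (1 - fA) + fB * (1 - fB)
            return (hb - hw) / hb
        fbar = self.fbar
        if estimator == "nei":
            return ((fA - fB) ** 2 / 4.0) / (fbar * (1.0 - fbar))
        if estimator == "plain":
            return (fA - fB) ** 2 / (2.0 * fbar * (1.0 - fbar))
        raise ValueError(f"unknown FST estimator: {estimator!r}")


@dataclass
class ArchitectureSpec:
    """A trait: source frequencies plus signed per-locus allelic effects."""

    freqs: SourceFrequencies
    beta: np.ndarray
    label: str = "neutral"
    criterion_value: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != self.freqs.f0.shape:
            raise ValueError("beta length must match number of loci")

    @property
    def m(self) -> int:
        return self.freqs.m

    @property
    def fbar(self) -> np.ndarray:
        return self.freqs.fbar

    @property
    def phi(self) -> np.ndarray:
        """Local-ancestry effect sizes phi_i = beta_i (f_iA - f_iB)."""
        return self.beta * (self.freqs.fA - self.freqs.fB)

    def with_signs(self, signs: np.ndarray, label: str | None = None) -> "ArchitectureSpec":
        """Return a copy with effect signs replaced by ``signs`` (+-1)."""
        return ArchitectureSpec(
            freqs=self.freqs,
            beta=np.abs(self.beta) * np.asarray(signs, dtype=float),
            label=self.label if label is None else label,
            criterion_value=np.nan,
        )


def draw_source_frequencies(
    m: int,
    F: float = 0.2,
    f0_range: tuple[float, float] = (0.001, 0.999),
    maf_bounds: tuple[float, float] = DEFAULT_MAF_BOUNDS,
    seed: int | np.random.Generator | None = None,
) -> SourceFrequencies:
    """Draw m loci under the Balding-Nichols model with rejection sampling.

    Loci are drawn as (f0, fA, fB) triples with f0 ~ Uniform(f0_range) and
    fA, fB independent Beta(f0(1-F)/F, (1-f0)(1-F)/F); a locus is retained
    only if both derived frequencies fall inside ``maf_bounds``, and fresh
    loci are drawn until m are retained.  Rejecting the whole locus (rather
    than redrawing fA, fB for a fixed f0) leaves the retained loci with the
    joint law the model implies conditional on being common in both
    populations, keeping the mean per-locus divergence at ~F.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < F < 1.0:
        raise ValueError("F must lie in (0, 1)")
    lo, hi = f0_range
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("f0_range must be a sub-interval of (0, 1)")
    blo, bhi = maf_bounds
    rng = np.random.default_rng(seed)

    kept: list[np.ndarray] = []
    n_kept = 0
    attempts = 0
    while n_kept < m:
        attempts += 1
        if attempts * m > MAX_REJECTION_ATTEMPTS * max(m, 1):
            raise RuntimeError(
                "rejection sampling failed to accumulate enough loci with "
                f"both population frequencies inside {maf_bounds}; widen "
                "maf_bounds or decrease F"
            )
        batch = max(m - n_kept, 64)
        f0 = rng.uniform(lo, hi, size=batch)
        a = f0 * (1.0 - F) / F
        b = (1.0 - f0) * (1.0 - F) / F
        fA = rng.beta(a, b)
        fB = rng.beta(a, b)
        ok = (fA > blo) & (fA < bhi) & (fB > blo) & (fB < bhi)
        if ok.any():
            kept.append(np.column_stack([f0[ok], fA[ok], fB[ok]]))
            n_kept += int(ok.sum())
    allk = np.concatenate(kept)[:m]
    return SourceFrequencies(f0=allk[:, 0], fA=allk[:, 1], fB=allk[:, 2], F=F)


def assign_effect_magnitudes(freqs: SourceFrequencies) -> np.ndarray:
    """Effect magnitudes beta_i = 1/sqrt(2 m fbar_i (1 - fbar_i)).

    The normalization makes sum_i 2 beta_i^2 fbar_i (1 - fbar_i) = 1: each
    locus contributes exactly 1/m of genic variance at the mean frequency.
    """
    fbar = freqs.fbar
    return 1.0 / np.sqrt(2.0 * freqs.m * fbar * (1.0 - fbar))


def _ld_contribution_stat(beta: np.ndarray, delta: np.ndarray) -> float:
    # sum_{i != j} beta_i beta_j delta_i delta_j  (the V(theta)-free core
    # of the directional-LD term)
    s = float(beta @ delta)
    return s * s - float((beta * delta) @ (beta * delta))


def permute_signs_select(
    freqs: SourceFrequencies,
    beta_mag: np.ndarray,
    n_perm: int = 100,
    criterion: str = "random",
    Etheta: float = 0.5,
    Vtheta: float = 0.25,
    seed: int | np.random.Generator | None = None,
) -> ArchitectureSpec:
    """Choose effect signs among ``n_perm`` random sign vectors.

    criterion is one of ``max_ld_contribution``, ``min_ld_contribution``,
    ``max_vgb``, ``min_vgb``, ``random``.  LD-contribution criteria score
    sign vectors by the directional-LD variance term
    4 V(theta) sum_{i != j} beta_i beta_j (f_iA - f_iB)(f_jA - f_jB);
    Vgb criteria score by the between-population genetic variance.  Ties
    break to the first draw.  The winning score is stored in
    ``criterion_value``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    known = {"max_ld_contribution", "min_ld_contribution", "max_vgb", "min_vgb", "random"}
    if criterion not in known:
        raise ValueError(f"unknown criterion {criterion!r}; expected one of {sorted(known)}")
    rng = np.random.default_rng(seed)
    beta_mag = np.abs(np.asarray(beta_mag, dtype=float))
    delta = freqs.fA - freqs.fB

    label = {
        "max_ld_contribution": "divergent",
        "max_vgb": "divergent",
        "min_ld_contribution": "stabilizing",
        "min_vgb": "stabilizing",
        "random": "neutral",
    }[criterion]

    def score(beta: np.ndarray) -> float:
        if criterion in ("max_ld_contribution", "min_ld_contribution"):
            return 4.0 * Vtheta * _ld_contribution_stat(beta, delta)
        gdiff = 2.0 * float(beta @ delta)
        return (gdiff / 2.0) ** 2  # Vgb

    best_beta = None
    best_score = None
    for _ in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=freqs.m)
        beta = beta_mag * signs
        if criterion == "random":
            best_beta, best_score = beta, score(beta)
            break
        s = score(beta)
        better = (
            best_score is None
            or (criterion.startswith("max") and s > best_score)
            or (criterion.startswith("min") and s < best_score)
        )
        if better:
            best_beta, best_score = beta, s
    return ArchitectureSpec(
        freqs=freqs, beta=best_beta, label=label, criterion_value=best_score
    )


def between_population_variance(arch: ArchitectureSpec) -> float:
    """Between-population genetic variance Vgb = ((gbarA - gbarB)/2)^2.

    gbarP = 2 sum_i beta_i f_iP is the mean genetic value in source
    population P.  Zero iff the mean genetic values are equal.  At
    E(theta)=0.5, V(theta)=0.25 (the founding 50/50 mixture) Vgb equals
    the sum of the three between-population terms of the variance
    decomposition.
    """
    gdiff = 2.0 * float(arch.beta @ (arch.freqs.fA - arch.freqs.fB))
    return (gdiff / 2.0) ** 2


# ---------------------------------------------------------------------------
# TSV round-trip

_COLUMNS = ["locus_id", "f0", "fA", "fB", "beta", "phi"]


def write_architecture(arch: ArchitectureSpec, path) -> None:
    """Write an architecture as TSV with columns locus_id, f0, fA, fB, beta, phi."""
    df = pd.DataFrame(
        {
            "locus_id": np.arange(arch.m),
            "f0": arch.freqs.f0,
            "fA": arch.freqs.fA,
            "fB": arch.freqs.fB,
            "beta": arch.beta,
            "phi": arch.phi,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_architecture(path, F: float = np.nan, label: str = "neutral") -> ArchitectureSpec:
    """Read an architecture TSV written by :func:`write_architecture`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"architecture file {path} missing columns: {missing}")
    freqs = SourceFrequencies(
        f0=df["f0"].to_numpy(), fA=df["fA"].to_numpy(), fB=df["fB"].to_numpy(), F=F
    )
    return ArchitectureSpec(freqs=freqs, beta=df["beta"].to_numpy(), label=label)
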