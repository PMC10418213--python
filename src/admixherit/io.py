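"""Text-based readers and writers for cohorts, GRMs and summary statistics.

Everything round-trips through plain TSV (plus sidecar JSON metadata for
cohorts) so that outputs are diff-able and portable.  Summary statistics
export in the conventional LDSC column layout (SNP, A1, A2, BETA, Z, N).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .admixsim import AdmixedCohort
from .estimators import SummaryStats

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_summary_stats",
    "read_summary_stats",
    "export_ldsc_sumstats",
]


def write_cohort(cohort: AdmixedCohort, outdir, meta: dict | None = None) -> None:
    """Write genotype and local-ancestry dosage TSVs plus JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "genotypes.tsv", cohort.X, fmt="%d", delimiter="\t")
    np.savetxt(outdir / "local_ancestry.tsv", cohort.gamma, fmt="%d", delimiter="\t")
    np.savetxt(outdir / "theta.tsv", cohort.theta, fmt="%.17g", delimiter="\t")
    record = {
        "t": cohort.t,
        "n": cohort.n,
        "m": cohort.m,
        "mating_flagged": bool(cohort.mating_flagged),
        "realized_P": None if np.isnan(cohort.realized_P) else float(cohort.realized_P),
    }
    if meta:
        record.update(meta)
    (outdir / "cohort.json").write_text(json.dumps(record, indent=2))


def read_cohort(outdir) -> AdmixedCohort:
    outdir = Path(outdir)
    meta = json.loads((outdir / "cohort.json").read_text())
    X = np.loadtxt(outdir / "genotypes.tsv", dtype=np.int8, delimiter="\t", ndmin=2)
    gamma = np.loadtxt(outdir / "local_ancestry.tsv", dtype=np.int8, delimiter="\t", ndmin=2)
    theta = np.loadtxt(outdir / "theta.tsv", delimiter="\t", ndmin=1)
    realized = meta.get("realized_P")
    return AdmixedCohort(
        t=int(meta["t"]),
        theta=theta,
        gamma=gamma,
        X=X,
        mating_flagged=bool(meta.get("mating_flagged", False)),
        realized_P=np.nan if realized is None else float(realized),
    )


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Native TSV with columns snp, a1, a0, beta, se, chi2, freq, n."""
    df = stats.table.copy()
    out = pd.DataFrame(
        {
            "snp": df["snp"],
            "a1": df.get("a1", "A"),
            "a0": df.get("a0", "G"),
            "beta": df["beta"],
            "se": df["se"],
            "chi2": df["chi2"],
            "freq": df["freq"],
            "n": stats.n,
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_summary_stats(path) -> SummaryStats:
    """Read a native summary-statistics TSV (columns matched by name)."""
    df = pd.read_csv(path, sep="\t")
    required = {"snp", "beta", "se", "chi2", "freq", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"summary-statistics file {path} is missing columns {sorted(missing)}; "
            f"found {list(df.columns)}"
        )
    n = int(df["n"].iloc[0])
    table = df[["snp", "beta", "se", "chi2", "freq"]].copy()
    table["flagged"] = ~np.isfinite(table["chi2"])
    return SummaryStats(table=table, n=n)


def export_ldsc_sumstats(stats: SummaryStats, path) -> None:
    """Export in the standard LDSC consumer layout: SNP A1 A2 BETA Z N."""
    df = stats.table
    z = np.sign(df["beta"]) * np.sqrt(df["chi2"])
    out = pd.DataFrame(
        {
            "SNP": df["snp"],
            "A1": df.get("a1", "A"),
            "A2": df.get("a0", "G"),
            "BETA": df["beta"],
            "Z": z,
            "N": stats.n,
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
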