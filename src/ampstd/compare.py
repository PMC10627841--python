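"""Statistics comparing quantifications from synthetic vs plasmid standards.

Per soil sample and gene: a two-sided unequal-variance (Welch) t-test on the
replicate copy numbers, Bonferroni adjustment over the samples of a gene,
the delta statistic

    delta = mean_plasmid / (mean_plasmid - mean_synthetic)

(large |delta| means the two standards agree closely; the sign says which
standard reads higher), and the percent difference relative to the plasmid
mean.  Per gene: the least-squares regression of log10 mean synthetic copies
on log10 mean plasmid copies (its r^2 is the cross-standard agreement
metric) and sample profiles normalized to the highest-copy soil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AmpstdError


@dataclass
class PairedQuant:
    """Replicate copy numbers for one sample quantified with both standards."""

    sample_id: str
    gene: str
    copies_synthetic: list[float]
    copies_plasmid: list[float]

    def __post_init__(self) -> None:
        for name, arm in (("synthetic", self.copies_synthetic),
                          ("plasmid", self.copies_plasmid)):
            if len(arm) == 0:
                raise AmpstdError(
                    f"{self.sample_id}/{self.gene}: empty {name} arm"
                )
            if any(v < 0 for v in arm):
                raise AmpstdError(
                    f"{self.sample_id}/{self.gene}: negative copies in {name} arm"
                )


@dataclass
class SampleComparison:
    sample_id: str
    gene: str
    mean_synthetic: float
    mean_plasmid: float
    t_statistic: float | None
    p_raw: float | None
    delta: float
    percent_difference: float
    p_adjusted: float | None = None


@dataclass
class ComparisonReport:
    per_sample: pd.DataFrame
    per_gene: pd.DataFrame
    m: int


def delta_statistic(mean_plasmid: float, mean_synthetic: float) -> float:
    """mean_p / (mean_p - mean_s); signed, infinite when the means agree."""
    diff = mean_plasmid - mean_synthetic
    if diff == 0:
        return math.inf
    return mean_plasmid / diff


def compare_sample(pq: PairedQuant, equal_var: bool = False) -> SampleComparison:
    """Welch (default) or pooled-variance two-sided t-test plus the
    delta/percent-difference descriptors.  With fewer than 2 replicates in
    either arm the test fields are None and only the descriptors are
    computed."""
    s = np.asarray(pq.copies_synthetic, dtype=float)
    p = np.asarray(pq.copies_plasmid, dtype=float)
    mean_s, mean_p = float(np.mean(s)), float(np.mean(p))
    t_stat = p_raw = None
    if s.size >= 2 and p.size >= 2:
        if np.std(s) == 0 and np.std(p) == 0 and mean_s == mean_p:
            t_stat, p_raw = 0.0, 1.0  # identical constant arms
        else:
            res = stats.ttest_ind(s, p, equal_var=equal_var)
            t_stat, p_raw = float(res.statistic), float(res.pvalue)
    pct = 100.0 * (mean_p - mean_s) / mean_p if mean_p != 0 else math.nan
    return SampleComparison(
        sample_id=pq.sample_id,
        gene=pq.gene,
        mean_synthetic=mean_s,
        mean_plasmid=mean_p,
        t_statistic=t_stat,
        p_raw=p_raw,
        delta=delta_statistic(mean_p, mean_s),
        percent_difference=pct,
    )


def adjust_bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni family-wise adjustment: p -> min(1, m*p), with m defaulting
    to the number of tests."""
    ps = list(p_values)
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise AmpstdError("p-values must lie in [0, 1]")
    m = len(ps) if m is None else m
    if m < 1:
        raise AmpstdError("m must be >= 1")
    return [min(1.0, m * p) for p in ps]


def correlate_standards(pqs: Sequence[PairedQuant]) -> pd.DataFrame:
    """Per-gene regression of log10(mean synthetic) on log10(mean plasmid).

    Samples with a non-positive mean in either arm are excluded (counted in
    ``n_excluded``); at least 3 usable samples per gene are required.
    """
    rows = []
    frame = pd.DataFrame([
        {
            "gene": pq.gene,
            "mean_s": float(np.mean(pq.copies_synthetic)),
            "mean_p": float(np.mean(pq.copies_plasmid)),
        }
        for pq in pqs
    ])
    if frame.empty:
        raise AmpstdError("no paired quantifications given")
    for gene, grp in frame.groupby("gene", sort=True):
        ok = grp[(grp["mean_s"] > 0) & (grp["mean_p"] > 0)]
        n_excluded = len(grp) - len(ok)
        if len(ok) < 3:
            raise AmpstdError(
                f"gene {gene!r}: need >= 3 samples with positive means, "
                f"got {len(ok)}"
            )
        fit = stats.linregress(np.log10(ok["mean_p"]), np.log10(ok["mean_s"]))
        rows.append({
            "gene": gene,
            "n_samples": len(ok),
            "n_excluded": n_excluded,
            "r_squared": float(fit.rvalue) ** 2,
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
        })
    return pd.DataFrame(rows)


def normalized_variation(pqs: Sequence[PairedQuant]) -> pd.DataFrame:
    """Per gene and standard, each sample's mean copies divided by the
    highest sample mean for that gene/standard (values in (0, 1]; ties all
    report 1.0)."""
    if len(pqs) < 2:
        raise AmpstdError("normalized_variation needs >= 2 samples")
    rows = []
    frame = pd.DataFrame([
        {
            "gene": pq.gene,
            "sample_id": pq.sample_id,
            "synthetic": float(np.mean(pq.copies_synthetic)),
            "plasmid": float(np.mean(pq.copies_plasmid)),
        }
        for pq in pqs
    ])
    for gene, grp in frame.groupby("gene", sort=True):
        for standard in ("synthetic", "plasmid"):
            top = grp[standard].max()
            if top <= 0:
                raise AmpstdError(f"gene {gene!r}: all-zero {standard} arm")
            for _, r in grp.iterrows():
                rows.append({
                    "gene": gene,
                    "sample_id": r["sample_id"],
                    "standard": standard,
                    "normalized": r[standard] / top,
                })
    return pd.DataFrame(rows)


def build_report(
    pqs: Sequence[PairedQuant],
    m: int | None = None,
    equal_var: bool = False,
) -> ComparisonReport:
    """Full synthetic-vs-plasmid comparison.

    Bonferroni's m defaults to the number of samples within each gene (the
    panel being adjusted over); pass ``m`` to override globally.
    """
    if not pqs:
        raise AmpstdError("no paired quantifications given")
    comps = [compare_sample(pq, equal_var=equal_var) for pq in pqs]
    by_gene: dict[str, list[SampleComparison]] = {}
    for c in comps:
        by_gene.setdefault(c.gene, []).append(c)
    for gene, group in by_gene.items():
        testable = [c for c in group if c.p_raw is not None]
        m_gene = m if m is not None else len(testable)
        if testable:
            adj = adjust_bonferroni([c.p_raw for c in testable], m_gene)
            for c, pa in zip(testable, adj):
                c.p_adjusted = pa

    per_sample = pd.DataFrame([
        {
            "sample_id": c.sample_id,
            "gene": c.gene,
            "mean_synthetic": c.mean_synthetic,
            "mean_plasmid": c.mean_plasmid,
            "t_statistic": c.t_statistic,
            "p_raw": c.p_raw,
            "p_adjusted": c.p_adjusted,
            "delta": c.delta,
            "percent_difference": c.percent_difference,
        }
        for c in comps
    ])

    gene_rows = []
    genes_ok = {
        g for g, grp in per_sample.groupby("gene")
        if len(grp) >= 3
    }
    corr = correlate_standards([pq for pq in pqs if pq.gene in genes_ok]) if genes_ok else pd.DataFrame()
    for gene, grp in per_sample.groupby("gene", sort=True):
        row = {
            "gene": gene,
            "mean_percent_difference": float(grp["percent_difference"].mean()),
            "sd_percent_difference": float(grp["percent_difference"].std(ddof=1))
            if len(grp) >= 2 else math.nan,
        }
        if not corr.empty and gene in set(corr["gene"]):
            crow = corr[corr["gene"] == gene].iloc[0]
            row.update({
                "correlation_r_squared": crow["r_squared"],
                "log_slope": crow["slope"],
                "log_intercept": crow["intercept"],
                "n_samples": int(crow["n_samples"]),
            })
        gene_rows.append(row)
    m_reported = m if m is not None else max(
        (len(g) for g in by_gene.values()), default=0
    )
    return ComparisonReport(
        per_sample=per_sample,
        per_gene=pd.DataFrame(gene_rows),
        m=m_reported,
    )


def paired_from_frames(
    synthetic: pd.DataFrame, plasmid: pd.DataFrame, copies_column: str | None = None
) -> list[PairedQuant]:
    """Build PairedQuant records from two per-replicate quantification tables
    (the schema written by the quantify stage: sample_id, gene, replicate,
    copies columns).  Uses copies per gram when present, else per uL."""
    def col(df: pd.DataFrame) -> str:
        if copies_column:
            return copies_column
        if "copies_per_g_dry_soil" in df.columns and df["copies_per_g_dry_soil"].notna().any():
            return "copies_per_g_dry_soil"
        return "copies_per_ul_template"

    out = []
    key = ["sample_id", "gene"]
    s_groups = synthetic.groupby(key)
    p_groups = plasmid.groupby(key)
    shared = sorted(set(s_groups.groups) & set(p_groups.groups))
    for k in shared:
        s_grp = s_groups.get_group(k)
        p_grp = p_groups.get_group(k)
        out.append(PairedQuant(
            sample_id=str(k[0]),
            gene=str(k[1]),
            copies_synthetic=s_grp[col(synthetic)].dropna().tolist(),
            copies_plasmid=p_grp[col(plasmid)].dropna().tolist(),
        ))
    return out
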