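"""Simulation of homologous gene families and qPCR dilution-series data.

Every other stage of the package can be exercised end-to-end without any
external download: :func:`simulate_family` emulates a set of 10-20 NCBI-style
homologs as descendants of a random ancestor with planted primer binding
sites, i.i.d. point substitutions and short geometric-length indels;
:func:`simulate_cq` emulates a qPCR run as Cq = b + m*log10(copies) plus
Gaussian noise, with an optional additive inhibition bias at the least
diluted levels and a hard dropout cutoff for non-amplification.  All
generators are pure functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AmpstdError
from .quantify import DilutionSeries, slope_from_efficiency
from .sequences import (
    DegeneratePrimer,
    IUPAC_SETS,
    NucSeq,
    reverse_complement,
    write_fasta,
)

_BASES = "ACGT"


@dataclass
class PlantedSite:
    """A concrete subsequence spliced into the ancestor at a fixed position."""

    sequence: str
    position: int


@dataclass
class FamilySimConfig:
    ancestor_length: int
    n_sequences: int = 15
    substitution_rate: float = 0.03
    indel_rate: float = 0.0
    indel_max_len: int = 6
    forward_site: PlantedSite | None = None
    reverse_site: PlantedSite | None = None
    protect_primer_sites: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate < 1 or not 0 <= self.indel_rate < 1:
            raise AmpstdError("rates must be in [0, 1)")
        if self.n_sequences < 1 or self.ancestor_length < 1:
            raise AmpstdError("need n_sequences >= 1 and ancestor_length >= 1")
        spans = []
        for site in (self.forward_site, self.reverse_site):
            if site is None:
                continue
            lo, hi = site.position, site.position + len(site.sequence)
            if lo < 0 or hi > self.ancestor_length:
                raise AmpstdError(f"planted site {site.sequence[:10]}... outside ancestor")
            spans.append((lo, hi))
        spans.sort()
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if c < b:
                raise AmpstdError("planted sites overlap")


def concretize(primer: DegeneratePrimer, rng: np.random.Generator) -> str:
    """Draw one concrete realisation of a degenerate primer (each degenerate
    code replaced by a uniformly chosen member base)."""
    return "".join(
        c if c in _BASES else rng.choice(sorted(IUPAC_SETS[c]))
        for c in primer.sequence5to3.residues
    )


def simulate_family(cfg: FamilySimConfig) -> tuple[list[NucSeq], dict]:
    """Simulate a homologous gene family.

    Returns the descendant sequences and a truth record holding the
    ancestor, the planted site coordinates, and per-sequence edit summaries.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestor = list(rng.choice(list(_BASES), size=cfg.ancestor_length))
    protected = np.zeros(cfg.ancestor_length, dtype=bool)
    sites = {}
    for name, site in (("forward", cfg.forward_site), ("reverse", cfg.reverse_site)):
        if site is None:
            continue
        lo = site.position
        hi = lo + len(site.sequence)
        ancestor[lo:hi] = list(site.sequence)
        sites[name] = {"start": lo, "end": hi, "sequence": site.sequence}
        if cfg.protect_primer_sites:
            protected[lo:hi] = True
    ancestor_str = "".join(ancestor)

    seqs: list[NucSeq] = []
    edits: list[dict] = []
    for i in range(cfg.n_sequences):
        n_sub = 0
        n_ins = n_del = 0
        out: list[str] = []
        pos = 0
        while pos < cfg.ancestor_length:
            base = ancestor_str[pos]
            if not protected[pos] and cfg.indel_rate > 0 and rng.random() < cfg.indel_rate:
                length = min(int(rng.geometric(0.5)), cfg.indel_max_len)
                if rng.random() < 0.5:
                    out.extend(rng.choice(list(_BASES), size=length))
                    n_ins += 1
                    # insertion precedes the current base, which still follows
                else:
                    # delete up to `length` unprotected bases from here
                    deleted = 0
                    while deleted < length and pos < cfg.ancestor_length and not protected[pos]:
                        pos += 1
                        deleted += 1
                    n_del += 1
                    continue
            if not protected[pos] and rng.random() < cfg.substitution_rate:
                choices = [b for b in _BASES if b != base]
                out.append(rng.choice(choices))
                n_sub += 1
            else:
                out.append(base)
            pos += 1
        seqs.append(NucSeq(f"homolog_{i + 1:02d}", "".join(out)))
        edits.append({"substitutions": n_sub, "insertions": n_ins, "deletions": n_del})

    truth = {
        "ancestor": ancestor_str,
        "sites": sites,
        "edits": edits,
        "config": {
            "ancestor_length": cfg.ancestor_length,
            "n_sequences": cfg.n_sequences,
            "substitution_rate": cfg.substitution_rate,
            "indel_rate": cfg.indel_rate,
            "indel_max_len": cfg.indel_max_len,
            "protect_primer_sites": cfg.protect_primer_sites,
            "seed": cfg.seed,
        },
    }
    return seqs, truth


def family_for_primer_pair(
    forward: DegeneratePrimer,
    reverse: DegeneratePrimer,
    inner_length: int,
    flank: int = 30,
    n_sequences: int = 15,
    substitution_rate: float = 0.03,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> FamilySimConfig:
    """Config for a family whose ancestor carries a concrete realisation of
    ``forward`` and of reverse_complement(``reverse``) separated by
    ``inner_length`` random bases, with ``flank`` bases on each side.  The
    implied amplicon length is len(forward) + inner_length + len(reverse)."""
    rng = np.random.default_rng(seed)
    fwd_concrete = concretize(forward, rng)
    rev_site = reverse_complement(
        NucSeq(reverse.name, concretize(reverse, rng))
    ).residues
    total = flank + len(fwd_concrete) + inner_length + len(rev_site) + flank
    return FamilySimConfig(
        ancestor_length=total,
        n_sequences=n_sequences,
        substitution_rate=substitution_rate,
        indel_rate=indel_rate,
        forward_site=PlantedSite(fwd_concrete, flank),
        reverse_site=PlantedSite(rev_site, flank + len(fwd_concrete) + inner_length),
        seed=seed,
    )


@dataclass
class QpcrSimConfig:
    """Ground-truth curve for Cq simulation.

    Give either ``true_slope`` (Cq per log10 copies) or ``true_efficiency``
    (fraction; converted via slope = -1/log10(1+E)).
    """

    true_intercept: float = 38.0
    true_slope: float | None = None
    true_efficiency: float | None = None
    cq_noise_sd: float = 0.15
    replicates: int = 3
    dropout_cq_cutoff: float = 40.0  # the assay's cycle count
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.true_slope is None) == (self.true_efficiency is None):
            raise AmpstdError("give exactly one of true_slope / true_efficiency")
        if self.true_slope is None:
            self.true_slope = slope_from_efficiency(self.true_efficiency)
        if self.cq_noise_sd < 0 or self.replicates < 1:
            raise AmpstdError("need cq_noise_sd >= 0 and replicates >= 1")


def simulate_cq(
    series: DilutionSeries,
    cfg: QpcrSimConfig,
    inhibition_bias: float = 0.0,
    biased_levels: int = 0,
) -> pd.DataFrame:
    """Replicate Cq table for a dilution series.

    Cq = intercept + slope*log10(copies) + N(0, sd), plus ``inhibition_bias``
    cycles at the ``biased_levels`` least-diluted (highest) levels.  Cq above
    the dropout cutoff is emitted as missing (NaN), modelling
    non-amplification within the cycle budget.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for idx, level in enumerate(series.levels):
        mu = cfg.true_intercept + cfg.true_slope * np.log10(level)
        if idx < biased_levels:
            mu += inhibition_bias
        for rep in range(1, cfg.replicates + 1):
            cq = mu + rng.normal(0.0, cfg.cq_noise_sd) if cfg.cq_noise_sd > 0 else mu
            rows.append({
                "level": level,
                "replicate": rep,
                "cq": np.nan if cq > cfg.dropout_cq_cutoff else cq,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Demo bundle

_BUNDLE_README = """\
ampstd demo bundle (seed {seed})
================================

Self-contained simulated inputs for the full workflow, one target gene
(nosZ, primer pair nosZ-1F / nosZ_1R):

  family.fasta          {n} simulated nosZ homologs (ancestor with planted
                        primer sites; substitutions + short indels)
  truth.json            simulation ground truth (ancestor, site coordinates)
  primers.csv           primer table row for nosZ
  plate_synthetic.csv   simulated qPCR plate: synthetic-standard dilution
                        series (10^8..10^1 copies/uL, triplicate) + 5 soil
                        samples in triplicate
  plate_plasmid.csv     same samples against a plasmid-standard series
  context.yaml          extraction bookkeeping for copies-per-gram conversion

Expected outcomes when run through the package: the consensus of
family.fasta contains both primer sites (0 mismatches), the designed
fragment is ~{frag} bp and valid; both standard curves fit with r^2 > 0.99
and efficiency within [0.9, 1.1]; synthetic-vs-plasmid quantifications
correlate with r^2 > 0.99 in log space.
"""


def make_demo_bundle(out_dir: str | Path, seed: int = 42) -> dict[str, Path]:
    """Write a deterministic, self-contained demo data set.

    Study conditions: 15 homologs, 3% substitution rate, 0.5% indel rate,
    nosZ amplicon geometry (249 bp); synthetic standard truth efficiency
    0.95 / intercept 38 Cq, plasmid truth efficiency 0.92 / intercept 37.5,
    Cq noise sd 0.15, triplicates, five soil samples spanning four orders of
    magnitude.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .sequences import bundled_primers

    fwd, rev = bundled_primers()["nosZ"]
    inner = 249 - len(fwd) - len(rev)
    fam_cfg = family_for_primer_pair(
        fwd, rev, inner_length=inner, flank=30, n_sequences=15,
        substitution_rate=0.03, indel_rate=0.005, seed=seed,
    )
    seqs, truth = simulate_family(fam_cfg)
    paths = {}
    paths["family"] = out / "family.fasta"
    write_fasta(seqs, paths["family"])
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")

    paths["primers"] = out / "primers.csv"
    paths["primers"].write_text(
        "gene,primer_name_f,primer_seq_f,primer_name_r,primer_seq_r\n"
        f"nosZ,{fwd.name},{fwd.sequence5to3.residues},"
        f"{rev.name},{rev.sequence5to3.residues}\n"
    )

    series = DilutionSeries([10.0 ** k for k in range(8, 0, -1)])
    sample_rng = np.random.default_rng(seed + 1)
    sample_copies = {
        f"soil_{i + 1}": 10.0 ** sample_rng.uniform(3.5, 7.0) for i in range(5)
    }
    std_truth = {
        "synthetic": QpcrSimConfig(true_efficiency=0.95, true_intercept=38.0,
                                   cq_noise_sd=0.15, seed=seed + 2),
        "plasmid": QpcrSimConfig(true_efficiency=0.92, true_intercept=37.5,
                                 cq_noise_sd=0.15, seed=seed + 3),
    }
    # the same soil reactions are read against either curve; sample Cq comes
    # from the synthetic-standard truth curve
    cq_rng = np.random.default_rng(seed + 4)
    sample_cq = {
        sid: [
            std_truth["synthetic"].true_intercept
            + std_truth["synthetic"].true_slope * np.log10(copies)
            + cq_rng.normal(0.0, 0.15)
            for _ in range(3)
        ]
        for sid, copies in sample_copies.items()
    }
    for kind, cfg in std_truth.items():
        std = simulate_cq(series, cfg)
        rows = []
        well = 1
        for _, r in std.iterrows():
            rows.append({
                "well": f"W{well:03d}", "role": "standard", "gene": "nosZ",
                "level_copies_per_ul": r["level"], "sample_id": "",
                "replicate": int(r["replicate"]), "cq": r["cq"],
            })
            well += 1
        for sid, cqs in sample_cq.items():
            for rep, cq in enumerate(cqs, start=1):
                rows.append({
                    "well": f"W{well:03d}", "role": "sample", "gene": "nosZ",
                    "level_copies_per_ul": "", "sample_id": sid,
                    "replicate": rep, "cq": cq,
                })
                well += 1
        rows.append({
            "well": f"W{well:03d}", "role": "NC", "gene": "nosZ",
            "level_copies_per_ul": "", "sample_id": "NC",
            "replicate": 1, "cq": np.nan,
        })
        paths[f"plate_{kind}"] = out / f"plate_{kind}.csv"
        pd.DataFrame(rows).to_csv(paths[f"plate_{kind}"], index=False)

    paths["context"] = out / "context.yaml"
    paths["context"].write_text(
        "template_dilution_factor: 10\n"
        "elution_volume: 100\n"
        "soil_dry_mass: 0.25\n"
        "template_volume: 2\n"
    )
    paths["readme"] = out / "README.txt"
    paths["readme"].write_text(
        _BUNDLE_README.format(seed=seed, n=fam_cfg.n_sequences, frag=309)
    )
    return paths
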