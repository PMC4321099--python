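"""Synthetic study generator.

Emulates the structure of a two-genotype-knockout ischemia-reperfusion
miRNA/mRNA array study: log-normal probe intensities with per-array scale
offsets, flagged bad spots, genotype- and timepoint-dependent planted fold
effects on miRNA arrays, planted miRNA->target repression that couples
whole-genome downregulation with Ago2-IP enrichment on two-color mRNA
arrays, and miRNA/3'UTR sequences carrying complementary target sites.

Every downstream stage of the pipeline is therefore testable against a
:class:`TruthLedger` without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .arrays import ArraySample, write_probe_table
from .errors import SimulationError
from .sequences import MiRNASeq, UTRSeq, reverse_complement

GENOTYPES = ("wildtype", "tlr4_ko", "nfkb_ko")
TIMEPOINTS = ("isc2h_rep0h", "rep4h", "rep1d", "rep7d")
RESPONSIVE_TIMEPOINT = "rep1d"

# decoy classes for the mRNA arms: each deliberately fails exactly one or two
# of the three evidence criteria
DECOY_DOWN_ONLY = "down_only"      # 2-fold down in total mRNA, flat in IP, no site
DECOY_IP_ONLY = "ip_only"          # 2-fold up in Ago2 IP, flat in total, no site
DECOY_SITE_ONLY = "site_only"      # planted sequence site, no expression effect


@dataclass
class SimDesign:
    """Study design and generative parameters.

    Defaults mirror the emulated study: three genotypes, four reperfusion
    timepoints, 3 miRNA-array replicates and 2 whole-genome replicates, with
    a 4-fold (log2 = 2) planted effect.
    """

    n_mirna_probes: int = 300
    n_genes: int = 100
    genotypes: tuple[str, ...] = GENOTYPES
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_replicates_mirna: int = 3
    n_replicates_mrna: int = 2
    n_responsive: int = 3
    n_upregulated: int = 5
    n_targets_per_mirna: int = 4
    n_target_genes: int | None = None
    n_decoys_per_class: int = 5
    effect_log2: float = 2.0
    noise_sd: float = 0.2
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    scale_offset_range: float = 0.5
    flag_fraction: float = 0.02
    utr_length: int = 500
    mirna_length: int = 22
    planted_site_span: int = 13
    lowess_curvature: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirna_probes", "n_genes", "n_replicates_mirna",
                     "n_replicates_mrna", "n_responsive", "n_upregulated",
                     "n_targets_per_mirna", "n_decoys_per_class"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.n_responsive + self.n_upregulated > self.n_mirna_probes:
            raise SimulationError(
                "n_responsive + n_upregulated exceeds n_mirna_probes; "
                "the planted effects cannot be realized")
        if not (0 <= self.flag_fraction < 1):
            raise SimulationError("flag_fraction must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be positive")

    @property
    def target_pool_size(self) -> int:
        if self.n_target_genes is not None:
            return self.n_target_genes
        return self.n_targets_per_mirna * self.n_responsive


@dataclass
class TruthLedger:
    """Ground truth planted by the simulator, for recovery scoring."""

    responsive_mirnas: set[str] = field(default_factory=set)
    upregulated_by_timepoint: dict[str, set[str]] = field(default_factory=dict)
    target_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_sites: list[tuple[str, int, str]] = field(default_factory=list)
    decoys: dict[str, set[str]] = field(default_factory=dict)

    @property
    def target_genes(self) -> set[str]:
        return {g for _, g in self.target_pairs}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("record\tfield1\tfield2\tfield3\n")
            for m in sorted(self.responsive_mirnas):
                fh.write(f"responsive\t{m}\t\t\n")
            for tp in sorted(self.upregulated_by_timepoint):
                for m in sorted(self.upregulated_by_timepoint[tp]):
                    fh.write(f"upregulated\t{tp}\t{m}\t\n")
            for m, g in sorted(self.target_pairs):
                fh.write(f"target_pair\t{m}\t{g}\t\n")
            for g, off, seq in sorted(self.planted_sites):
                fh.write(f"planted_site\t{g}\t{off}\t{seq}\n")
            for cls in sorted(self.decoys):
                for g in sorted(self.decoys[cls]):
                    fh.write(f"decoy\t{cls}\t{g}\t\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthLedger":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        ledger = cls()
        for row in df.itertuples(index=False):
            if row.record == "responsive":
                ledger.responsive_mirnas.add(row.field1)
            elif row.record == "upregulated":
                ledger.upregulated_by_timepoint.setdefault(row.field1, set()).add(row.field2)
            elif row.record == "target_pair":
                ledger.target_pairs.add((row.field1, row.field2))
            elif row.record == "planted_site":
                ledger.planted_sites.append((row.field1, int(row.field2), row.field3))
            elif row.record == "decoy":
                ledger.decoys.setdefault(row.field1, set()).add(row.field2)
        return ledger


_STREAM_NAMES = ("mirna_truth", "mrna_truth", "mirna_baselines", "mrna_baselines",
                 "mirna_arrays", "mrna_arrays", "mirna_flags", "mrna_flags",
                 "sequences")


def _streams(design: SimDesign) -> dict[str, np.random.Generator]:
    """Deterministic per-purpose RNG streams derived from the master seed."""
    root = np.random.SeedSequence(design.seed)
    children = root.spawn(len(_STREAM_NAMES))
    return {name: np.random.default_rng(child)
            for name, child in zip(_STREAM_NAMES, children)}


def _mirna_ids(design: SimDesign) -> list[str]:
    return [f"miR-sim-{i:04d}" for i in range(design.n_mirna_probes)]


def _gene_ids(design: SimDesign) -> list[str]:
    return [f"gene-{i:04d}" for i in range(design.n_genes)]


# ---------------------------------------------------------------------------
# miRNA arrays
# ---------------------------------------------------------------------------

def simulate_mirna_arrays(design: SimDesign
                          ) -> tuple[list[ArraySample], TruthLedger]:
    """Generate single-channel miRNA arrays for every design cell.

    One array per (genotype, timepoint, replicate, condition in {iri, sham}).
    Planted truth:

    * responsive miRNAs carry +effect_log2 (IRI vs sham) in wild type and
      -effect_log2 in both knockouts, at the 1-day reperfusion timepoint;
    * non-responsive planted upregulated miRNAs carry +effect_log2 in all
      genotypes at every timepoint where they are planted;
    * a ``flag_fraction`` of spots receives flag -50 at random.
    """
    rngs = _streams(design)
    features = np.array(_mirna_ids(design))
    picked = rngs["mirna_truth"].choice(design.n_mirna_probes,
                                  size=design.n_responsive + design.n_upregulated,
                                  replace=False)
    responsive = {str(f) for f in features[picked[:design.n_responsive]]}
    upregulated = {str(f) for f in features[picked[design.n_responsive:]]}
    ledger = TruthLedger(responsive_mirnas=responsive)
    for tp in design.timepoints:
        planted_here = set(upregulated)
        if tp == RESPONSIVE_TIMEPOINT:
            planted_here |= responsive
        ledger.upregulated_by_timepoint[tp] = planted_here

    baseline = rngs["mirna_baselines"].normal(design.baseline_log2_mean,
                                              design.baseline_log2_sd,
                                              size=design.n_mirna_probes)
    is_responsive = np.isin(features, sorted(responsive))
    is_upregulated = np.isin(features, sorted(upregulated))

    arr_rng, flag_rng = rngs["mirna_arrays"], rngs["mirna_flags"]
    samples: list[ArraySample] = []
    for genotype in design.genotypes:
        for tp in design.timepoints:
            for rep in range(design.n_replicates_mirna):
                for condition in ("iri", "sham"):
                    effect = np.zeros(design.n_mirna_probes)
                    if condition == "iri":
                        effect[is_upregulated] = design.effect_log2
                        if tp == RESPONSIVE_TIMEPOINT:
                            sign = 1.0 if genotype == "wildtype" else -1.0
                            effect[is_responsive] = sign * design.effect_log2
                    scale = arr_rng.uniform(-design.scale_offset_range,
                                            design.scale_offset_range)
                    log2_int = (baseline + effect + scale
                                + arr_rng.normal(0, design.noise_sd,
                                                 design.n_mirna_probes))
                    flags = np.where(
                        flag_rng.random(design.n_mirna_probes) < design.flag_fraction,
                        -50, 0)
                    probes = pd.DataFrame({
                        "probe_id": [f"P{i:04d}" for i in range(design.n_mirna_probes)],
                        "feature_id": features,
                        "cy5": np.exp2(log2_int),
                        "cy3": np.nan,
                        "flag": flags,
                    })
                    samples.append(ArraySample(
                        sample_id=f"mirna:{genotype}:{tp}:{condition}:r{rep}",
                        arm="mirna", condition=condition, probes=probes,
                        genotype=genotype, timepoint=tp, replicate=rep))
    return samples, ledger


# ---------------------------------------------------------------------------
# mRNA arrays (total + Ago2 IP)
# ---------------------------------------------------------------------------

def simulate_mrna_arrays(design: SimDesign, ledger: TruthLedger
                         ) -> list[ArraySample]:
    """Generate two-color whole-genome arrays (total mRNA and Ago2-IP arms).

    Extends ``ledger`` in place with target pairs and decoy classes.  Every
    planted target gene is >= 2-fold down in the total-mRNA arm and >= 2-fold
    up in the Ago2-IP arm (log2 effects -/+ ``effect_log2``); decoy genes
    satisfy exactly one expression criterion or none (site-only).
    """
    if ledger is None or not ledger.responsive_mirnas:
        raise SimulationError("ledger with responsive miRNAs required; "
                              "run simulate_mirna_arrays first")
    rngs = _streams(design)
    truth_rng = rngs["mrna_truth"]
    genes = np.array(_gene_ids(design))
    pool_size = design.target_pool_size
    n_special = pool_size + 3 * design.n_decoys_per_class
    if n_special > design.n_genes:
        raise SimulationError(
            f"need {n_special} target+decoy genes but only {design.n_genes} genes")
    special = truth_rng.choice(design.n_genes, size=n_special, replace=False)
    target_pool = genes[special[:pool_size]]
    cursor = pool_size
    for cls in (DECOY_DOWN_ONLY, DECOY_IP_ONLY, DECOY_SITE_ONLY):
        ledger.decoys[cls] = {str(g) for g in
                              genes[special[cursor:cursor + design.n_decoys_per_class]]}
        cursor += design.n_decoys_per_class

    for mirna in sorted(ledger.responsive_mirnas):
        chosen = truth_rng.choice(pool_size,
                                  size=min(design.n_targets_per_mirna, pool_size),
                                  replace=False)
        for g in target_pool[chosen]:
            ledger.target_pairs.add((str(mirna), str(g)))
    # a gene drawn into the pool but never picked by any miRNA is not a target
    target_genes = ledger.target_genes

    baseline = rngs["mrna_baselines"].normal(design.baseline_log2_mean,
                                             design.baseline_log2_sd,
                                             size=design.n_genes)
    effect_total = np.zeros(design.n_genes)
    effect_ip = np.zeros(design.n_genes)
    for i, g in enumerate(genes):
        if g in target_genes:
            effect_total[i] = -design.effect_log2
            effect_ip[i] = design.effect_log2
        elif g in ledger.decoys[DECOY_DOWN_ONLY]:
            effect_total[i] = -design.effect_log2
        elif g in ledger.decoys[DECOY_IP_ONLY]:
            effect_ip[i] = design.effect_log2

    arr_rng, flag_rng = rngs["mrna_arrays"], rngs["mrna_flags"]
    samples: list[ArraySample] = []
    for arm, effect in (("mrna_total", effect_total), ("mrna_ago2ip", effect_ip)):
        for rep in range(design.n_replicates_mrna):
            scale = arr_rng.uniform(-design.scale_offset_range,
                                    design.scale_offset_range)
            log2_cy3 = (baseline + scale
                        + arr_rng.normal(0, design.noise_sd, design.n_genes))
            log2_cy5 = (baseline + effect + scale
                        + arr_rng.normal(0, design.noise_sd, design.n_genes))
            if design.lowess_curvature:
                a = 0.5 * (log2_cy5 + log2_cy3)
                log2_cy5 = log2_cy5 + design.lowess_curvature * (a - a.mean())
            flags = np.where(flag_rng.random(design.n_genes) < design.flag_fraction,
                             -50, 0)
            probes = pd.DataFrame({
                "probe_id": [f"G{i:04d}" for i in range(design.n_genes)],
                "feature_id": genes,
                "cy5": np.exp2(log2_cy5),
                "cy3": np.exp2(log2_cy3),
                "flag": flags,
            })
            samples.append(ArraySample(
                sample_id=f"{arm}:{RESPONSIVE_TIMEPOINT}:iri:r{rep}",
                arm=arm, condition="iri", probes=probes,
                genotype="wildtype", timepoint=RESPONSIVE_TIMEPOINT, replicate=rep))
    return samples


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

_RNA = np.array(list("ACGU"))


def simulate_sequences(design: SimDesign, ledger: TruthLedger
                       ) -> tuple[list[MiRNASeq], list[UTRSeq]]:
    """Generate miRNA and 3'UTR FASTA sequences with planted target sites.

    UTR backgrounds are i.i.d. uniform nucleotides.  Each (miRNA, gene)
    target pair — and each site-only decoy — receives one planted site: the
    reverse complement of the miRNA's first ``planted_site_span`` nucleotides
    (which contains the reverse complement of the seed, positions 2-8),
    embedded at a recorded offset.  Sites for distinct miRNAs in the same UTR
    occupy disjoint windows.  Extends ``ledger.planted_sites`` in place.
    """
    if ledger is None:
        raise SimulationError("ledger required; run simulate_mirna_arrays first")
    rng = _streams(design)["sequences"]
    span = design.planted_site_span
    if span > design.utr_length:
        raise SimulationError("planted site span exceeds UTR length")
    sequenced = sorted(ledger.responsive_mirnas
                       | ledger.upregulated_by_timepoint.get(RESPONSIVE_TIMEPOINT, set()))
    mirnas = {m: MiRNASeq(m, "".join(rng.choice(_RNA, size=design.mirna_length)))
              for m in sequenced}

    site_plan: dict[str, list[str]] = {}
    for m, g in sorted(ledger.target_pairs):
        site_plan.setdefault(g, []).append(m)
    decoy_mirnas = sorted(ledger.responsive_mirnas)
    for i, g in enumerate(sorted(ledger.decoys.get(DECOY_SITE_ONLY, set()))):
        site_plan.setdefault(g, []).append(decoy_mirnas[i % len(decoy_mirnas)])

    utrs = []
    for g in _gene_ids(design):
        seq = rng.choice(_RNA, size=design.utr_length)
        planted = site_plan.get(g, [])
        if planted:
            window = design.utr_length // len(planted)
            if window < span:
                raise SimulationError(
                    f"{g}: cannot place {len(planted)} non-overlapping sites of "
                    f"span {span} in a UTR of length {design.utr_length}")
            for k, m in enumerate(planted):
                offset = k * window + int(rng.integers(0, window - span + 1))
                if offset + span > design.utr_length:
                    raise SimulationError(f"{g}: site offset beyond UTR length")
                site = reverse_complement(mirnas[m].sequence[:span])
                seq[offset:offset + span] = list(site)
                ledger.planted_sites.append((g, offset, site))
        utrs.append(UTRSeq(g, "".join(seq), accession=f"NM_SIM{g[-4:]}"))
    return list(mirnas.values()), utrs


# ---------------------------------------------------------------------------
# Whole-study convenience wrapper + on-disk layout
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    design: SimDesign
    mirna_samples: list[ArraySample]
    mrna_samples: list[ArraySample]
    mirnas: list[MiRNASeq]
    utrs: list[UTRSeq]
    ledger: TruthLedger


def simulate_study(design: SimDesign) -> SimulatedStudy:
    """Run all three generators under one design and master seed."""
    mirna_samples, ledger = simulate_mirna_arrays(design)
    mrna_samples = simulate_mrna_arrays(design, ledger)
    mirnas, utrs = simulate_sequences(design, ledger)
    return SimulatedStudy(design, mirna_samples, mrna_samples, mirnas, utrs, ledger)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write probe tables, a manifest, FASTA sequences and the truth ledger.

    Output is byte-deterministic for a fixed design (including seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for sample in study.mirna_samples + study.mrna_samples:
        fname = sample.sample_id.replace(":", "_") + ".tsv"
        write_probe_table(sample, outdir / fname)
        manifest_rows.append((fname, sample.sample_id, sample.genotype or "",
                              sample.timepoint or "", str(sample.replicate),
                              sample.arm, sample.condition))
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("filename\tsample_id\tgenotype\ttimepoint\treplicate\tarm\tcondition\n")
        for row in manifest_rows:
            fh.write("\t".join(row) + "\n")
    with open(outdir / "mirnas.fa", "w") as fh:
        for m in study.mirnas:
            fh.write(f">{m.id}\n{m.sequence}\n")
    with open(outdir / "utrs.fa", "w") as fh:
        for u in study.utrs:
            fh.write(f">{u.gene_id} {u.accession}\n{u.sequence}\n")
    study.ledger.to_tsv(outdir / "truth_ledger.tsv")


def read_study_samples(outdir: str | Path) -> list[ArraySample]:
    """Load every probe table listed in a study directory's manifest."""
    from .arrays import read_probe_table
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.tsv", sep="\t",
                           keep_default_na=False)
    samples = []
    for row in manifest.itertuples(index=False):
        samples.append(read_probe_table(
            outdir / row.filename, sample_id=row.sample_id, arm=row.arm,
            condition=row.condition, genotype=row.genotype or None,
            timepoint=row.timepoint or None, replicate=int(row.replicate)))
    return samples
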