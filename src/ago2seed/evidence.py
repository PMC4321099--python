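"""Evidence triangulation: the final target-calling intersection.

A (miRNA, gene) pair is called a potential target only when three
independent lines of evidence concur:

1. an in silico duplex site prediction for that miRNA in the gene's 3'UTR;
2. >= 2-fold enrichment of the transcript in the Ago2-IP arm (the mRNA is
   physically engaged by the silencing machinery after injury);
3. >= 2-fold downregulation of the transcript on the whole-genome array
   (consistent with miRNA-directed degradation).

The module also tabulates per-gene multiplicity (genes called by >= k
distinct miRNAs) and ships the study's printed reference tables as packaged
fixtures for worked-example reproduction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .errors import FixtureError

_FIXTURE_SHA256 = {
    "table1_upregulated_mirnas.tsv":
        "8b744eb83591400b0e2650abe3af6ec22a4bf0c43ccef253eb9f26ed68293914",
    "table2_genotype_folds.tsv":
        "bac84b644fb03e8e2d67088e4510d280b46de72bfdda1b949b839dd14e135a7d",
    "table3_target_genes.tsv":
        "3e6371cb33720758f9632227eef1285c6a311762f09e9ad2e2d0a616e46382d4",
}


def _harmonize(symbol: str) -> str:
    """Case-insensitive gene symbol key."""
    return symbol.strip().casefold()


def intersect_evidence(predicted: Mapping[str, Iterable[str]],
                       ago2_up: Iterable[str], mrna_down: Iterable[str],
                       accessions: Mapping[str, str] | None = None
                       ) -> pd.DataFrame:
    """Full-outer evidence table over every (miRNA, candidate gene) pair.

    Gene identifiers are matched case-insensitively on symbol; when an
    ``accessions`` map is given, a symbol mapping to conflicting accessions
    across inputs is reported and excluded from calls rather than silently
    merged.  ``called`` is the strict conjunction of the three evidence bits.
    """
    up_keys = {_harmonize(g): g for g in ago2_up}
    down_keys = {_harmonize(g): g for g in mrna_down}
    accession_of: dict[str, str] = {}
    conflicted: set[str] = set()
    if accessions:
        for symbol, acc in accessions.items():
            key = _harmonize(symbol)
            if key in accession_of and accession_of[key] != acc:
                conflicted.add(key)
            accession_of[key] = acc
    rows = []
    for mirna in sorted(predicted):
        pred_keys = {_harmonize(g): g for g in predicted[mirna]}
        universe = sorted(set(pred_keys) | set(up_keys) | set(down_keys))
        for key in universe:
            symbol = pred_keys.get(key) or up_keys.get(key) or down_keys.get(key)
            is_pred = key in pred_keys
            is_up = key in up_keys
            is_down = key in down_keys
            called = is_pred and is_up and is_down and key not in conflicted
            rows.append((mirna, symbol, accession_of.get(key, ""),
                         is_pred, is_up, is_down, called))
    table = pd.DataFrame(rows, columns=["mirna", "gene", "accession",
                                        "predicted", "ago2_up", "mrna_down",
                                        "called"])
    if conflicted:
        import logging
        logging.getLogger(__name__).warning(
            "identifier collisions excluded from calls: %s",
            ", ".join(sorted(conflicted)))
    return table


def called_targets(table: pd.DataFrame) -> dict[str, list[str]]:
    """Per-miRNA sorted lists of called target genes."""
    called = table[table["called"]]
    return {m: sorted(g["gene"]) for m, g in called.groupby("mirna")}


@dataclass
class MultiplicitySummary:
    """Per-gene count of calling miRNAs and the genes at or above k."""

    counts: dict[str, int]
    k: int
    genes_at_k: list[str]

    def __len__(self) -> int:
        return len(self.genes_at_k)


def multiplicity(table: pd.DataFrame, k: int = 2) -> MultiplicitySummary:
    """Genes called by at least ``k`` distinct miRNAs.

    ``genes_at_k`` is sorted by (count desc, gene id).
    """
    called = table[table["called"]]
    counts = (called.groupby("gene")["mirna"].nunique().to_dict())
    genes = sorted((g for g, c in counts.items() if c >= k),
                   key=lambda g: (-counts[g], g))
    return MultiplicitySummary(counts=counts, k=k, genes_at_k=genes)


# ---------------------------------------------------------------------------
# Packaged printed-table fixtures
# ---------------------------------------------------------------------------

def _load_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("ago2seed.data").joinpath(name)
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:
        raise FixtureError(f"packaged fixture {name} is missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureError(f"fixture {name} is corrupted (sha256 {digest})")
    from io import BytesIO
    return pd.read_csv(BytesIO(raw), sep="\t")


def load_table1_fixture() -> pd.DataFrame:
    """Upregulated-miRNA lists per (timepoint, threshold) column, as printed.

    Columns: ``timepoint`` (isc2h_rep0h, rep4h, rep1d, rep7d), ``threshold``
    (the printed log2-ratio column header) and ``mirna``.  Duplicate listings
    are preserved exactly as printed.
    """
    return _load_fixture("table1_upregulated_mirnas.tsv")


def load_table2_fixture() -> pd.DataFrame:
    """Per-genotype log2 fold table for the three responsive miRNAs.

    Indexed by miRNA with columns ``wildtype, tlr4_ko, nfkb_ko``.
    """
    return _load_fixture("table2_genotype_folds.tsv").set_index("mirna")


def load_table3_fixture() -> dict[str, pd.DataFrame]:
    """Printed per-miRNA potential-target lists.

    Returns a dict mapping miRNA id to a DataFrame with columns
    ``accession, gene, definition``, preserving printed order.
    """
    df = _load_fixture("table3_target_genes.tsv")
    return {m: g[["accession", "gene", "definition"]].reset_index(drop=True)
            for m, g in df.groupby("mirna", sort=True)}


def write_evidence_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_multiplicity(summary: MultiplicitySummary, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# k={summary.k}; genes_at_k={len(summary.genes_at_k)}\n")
        fh.write("gene\tn_mirnas\tat_k\n")
        for gene in sorted(summary.counts, key=lambda g: (-summary.counts[g], g)):
            fh.write(f"{gene}\t{summary.counts[gene]}"
                     f"\t{int(gene in summary.genes_at_k)}\n")
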