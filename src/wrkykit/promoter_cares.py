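"""Promoter extraction and cis-acting regulatory element (CARE) scanning.

Promoters are the 1,500 bp immediately upstream of the translational start
(the first CDS base), truncated with a warning at contig edges.  Scanning
is exact degenerate matching: each motif consensus is an IUPAC nucleotide
string expanded to a character class, matched on both strands with
overlaps allowed.  The shipped dictionary follows published PlantCARE
entries (variable-length elements are represented by a canonical core);
matching semantics are defined against the shipped consensus strings.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

from .genome_context import GeneModel

__all__ = [
    "CareMotif",
    "PromoterHit",
    "CATEGORIES",
    "load_care_motifs",
    "extract_promoter",
    "scan_cares",
    "scan_promoter_set",
    "care_summary",
]

CATEGORIES = ("essential", "enhancer", "light", "tissue", "abiotic", "hormone", "other")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class CareConfigError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CareMotif:
    name: str
    consensus: str
    category: str
    description: str = ""

    def __post_init__(self):
        if len(self.consensus) < 4:
            raise CareConfigError(f"{self.name}: consensus shorter than 4 nt")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise CareConfigError(
                f"{self.name}: invalid IUPAC code(s) {sorted(bad)}"
            )
        if self.category not in CATEGORIES:
            raise CareConfigError(f"{self.name}: unknown category {self.category!r}")

    def regex(self) -> str:
        return "".join(
            c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in self.consensus.upper()
        )


@dataclass(frozen=True)
class PromoterHit:
    gene_id: str
    motif: str
    strand: str  # "+" | "-"
    offset: int  # 1-based position within the promoter (forward coordinates)
    matched: str  # sequence as matched on the reported strand


def load_care_motifs(path=None) -> list:
    """Motif dictionary from TSV (name, consensus, category[, description])."""
    if path is None:
        with resources.files("wrkykit.data").joinpath("care_motifs.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    motifs = []
    for _, row in df.iterrows():
        motifs.append(
            CareMotif(
                name=str(row["name"]),
                consensus=str(row["consensus"]).upper(),
                category=str(row["category"]),
                description=str(row.get("description", "") or ""),
            )
        )
    return motifs


# ---------------------------------------------------------------------------
# promoter extraction


def extract_promoter(
    gene: GeneModel, genome: Mapping[str, str], length: int = 1500
) -> str:
    """Upstream promoter of the translational start, 5'->3' on the coding strand."""
    if gene.chrom not in genome:
        raise KeyError(f"{gene.gene_id}: chromosome {gene.chrom!r} not in genome")
    if not gene.cds:
        raise ValueError(f"{gene.gene_id}: gene model has no CDS")
    seq = genome[gene.chrom]
    if gene.strand == "+":
        first = min(s for s, _ in gene.cds)  # 1-based first CDS base
        lo = max(0, first - 1 - length)
        promoter = seq[lo : first - 1]
    else:
        last = max(e for _, e in gene.cds)  # rightmost CDS base
        promoter = revcomp(seq[last : last + length])
    if len(promoter) < length:
        warnings.warn(
            f"{gene.gene_id}: promoter truncated to {len(promoter)} bp at contig edge"
        )
    return promoter.upper()


# ---------------------------------------------------------------------------
# scanning


def scan_cares(
    promoter: str,
    motifs: Sequence[CareMotif],
    both_strands: bool = True,
    gene_id: str = "",
) -> list:
    """All degenerate-exact motif matches; offsets are forward 1-based.

    Minus-strand hits report the forward-strand position of the matched
    window and the matching (reverse-complement) sequence.
    """
    promoter = promoter.upper()
    hits = []
    for m in motifs:
        pat = re.compile(f"(?=({m.regex()}))")
        for match in pat.finditer(promoter):
            hits.append(
                PromoterHit(
                    gene_id=gene_id,
                    motif=m.name,
                    strand="+",
                    offset=match.start() + 1,
                    matched=match.group(1),
                )
            )
        if both_strands:
            rc = revcomp(promoter)
            L = len(promoter)
            for match in pat.finditer(rc):
                w = len(match.group(1))
                fwd_start = L - match.start() - w  # 0-based forward window start
                hits.append(
                    PromoterHit(
                        gene_id=gene_id,
                        motif=m.name,
                        strand="-",
                        offset=fwd_start + 1,
                        matched=match.group(1),
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.motif, h.strand))
    return hits


def scan_promoter_set(
    promoters: Mapping[str, str],
    motifs: Sequence[CareMotif],
    both_strands: bool = True,
) -> list:
    hits = []
    for gene_id in promoters:
        hits.extend(
            scan_cares(promoters[gene_id], motifs, both_strands, gene_id=gene_id)
        )
    return hits


# ---------------------------------------------------------------------------
# summaries


def care_summary(hits: Sequence[PromoterHit], motifs: Sequence[CareMotif]) -> pd.DataFrame:
    """Per-gene distinct-element counts per category.

    A motif hit several times in one promoter counts once (element types,
    not instances); use :func:`care_instance_counts` for instance counts.
    """
    cat = {m.name: m.category for m in motifs}
    genes = sorted({h.gene_id for h in hits})
    seen: dict = {g: set() for g in genes}
    for h in hits:
        seen[h.gene_id].add(h.motif)
    rows = []
    for g in genes:
        row = {"gene_id": g}
        for c in CATEGORIES:
            row[c] = sum(1 for name in seen[g] if cat.get(name) == c)
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene_id", *CATEGORIES])


def care_instance_counts(hits: Sequence[PromoterHit]) -> pd.DataFrame:
    """Per-gene, per-motif hit instance counts."""
    rows: dict = {}
    for h in hits:
        rows[(h.gene_id, h.motif)] = rows.get((h.gene_id, h.motif), 0) + 1
    return pd.DataFrame(
        [{"gene_id": g, "motif": m, "n_hits": n} for (g, m), n in sorted(rows.items())],
        columns=["gene_id", "motif", "n_hits"],
    )


def hits_to_table(hits: Sequence[PromoterHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "motif": h.motif,
                "strand": h.strand,
                "offset": h.offset,
                "matched": h.matched,
            }
            for h in hits
        ],
        columns=["gene_id", "motif", "strand", "offset", "matched"],
    )


def hits_to_gff3(hits: Sequence[PromoterHit]) -> str:
    """Hits as GFF3 with coordinates relative to the promoter (1-based)."""
    lines = ["##gff-version 3"]
    for h in hits:
        end = h.offset + len(h.matched) - 1
        lines.append(
            f"{h.gene_id}\twrkykit\tregulatory_region\t{h.offset}\t{end}\t.\t"
            f"{h.strand}\t.\tName={h.motif}"
        )
    return "\n".join(lines) + "\n"
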