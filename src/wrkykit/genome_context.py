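"""Gene models, exon/intron structure, and chromosomal gene clusters.

Family genes often sit in small tandem clusters.  The clustering rule used
here links two neighbouring family genes when their intergenic gap is
below ``max_gap_bp`` (default 200 kb, strict) AND at most
``max_intervening_genes`` (default 8, inclusive) non-family genes lie
fully between them; clusters are maximal linked runs of two or more.

Coordinates are 1-based inclusive at every external interface (the GFF3
dialect); BED export is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "GeneModel",
    "GeneCluster",
    "ClusterRule",
    "read_gene_models",
    "structure_stats",
    "detect_clusters",
    "chromosome_distribution",
    "clusters_to_bed",
    "clusters_to_table",
]


class Gff3ParseError(ValueError):
    pass


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    exons: list = field(default_factory=list)  # [(start, end), ...] sorted
    cds: list = field(default_factory=list)
    is_family_member: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise Gff3ParseError(f"{self.gene_id}: unknown strand {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise Gff3ParseError(
                    f"{self.gene_id}: exon {s}-{e} outside gene span "
                    f"{self.start}-{self.end}"
                )
            if prev_end is not None and s <= prev_end:
                raise Gff3ParseError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        self.cds = sorted(self.cds)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return max(0, len(self.exons) - 1)


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    chrom: str
    members: tuple  # ordered gene ids, >= 2
    span_bp: int

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a cluster needs >= 2 members")


@dataclass(frozen=True)
class ClusterRule:
    max_gap_bp: int = 200_000
    max_intervening_genes: int = 8

    def __post_init__(self):
        if self.max_gap_bp <= 0 or self.max_intervening_genes <= 0:
            raise ValueError("cluster rule parameters must be positive")


# ---------------------------------------------------------------------------
# GFF3 input


def read_gene_models(
    source, family_ids: Optional[Iterable[str]] = None, from_string: bool = False
) -> list:
    """Parse GFF3 into gene models, keeping the longest mRNA's exon set.

    "Longest" means greatest summed exon length, ties broken by more exons
    then mRNA id.  Genes without an mRNA/exon child get a single exon
    covering the gene span.  Output is stably sorted by (chrom, start).
    """
    import gffutils

    db = gffutils.create_db(
        str(source) if not from_string else source,
        dbfn=":memory:",
        from_string=from_string,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    family = set(family_ids) if family_ids is not None else set()
    genes = []
    for g in db.features_of_type("gene"):
        best = None  # (exon_bp, n_exons, mrna_id, exons, cds)
        for m in db.children(g, featuretype=("mRNA", "transcript")):
            exons = [(f.start, f.end) for f in db.children(m, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(m, featuretype="CDS")]
            if not exons:
                exons = cds[:]
            if not exons:
                continue
            cand = (
                sum(e - s + 1 for s, e in exons),
                len(exons),
                m.id,
                sorted(exons),
                sorted(cds),
            )
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
        if best is None:
            exons = [(g.start, g.end)]
            cds = []
        else:
            exons, cds = best[3], best[4]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand,
                exons=exons,
                cds=cds,
                is_family_member=g.id in family,
            )
        )
    genes.sort(key=lambda gm: (gm.chrom, gm.start, gm.gene_id))
    return genes


def write_gff3(genes: Sequence[GeneModel], handle) -> None:
    """Serialize gene models (gene/mRNA/exon/CDS) back to GFF3 text."""
    close = False
    if isinstance(handle, (str, bytes)) or hasattr(handle, "__fspath__"):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            handle.write(
                f"{g.chrom}\twrkykit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mid = f"{g.gene_id}.1"
            handle.write(
                f"{g.chrom}\twrkykit\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                handle.write(
                    f"{g.chrom}\twrkykit\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={mid}\n"
                )
            for s, e in g.cds:
                handle.write(
                    f"{g.chrom}\twrkykit\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\tParent={mid}\n"
                )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# structure statistics


def structure_stats(genes: Sequence[GeneModel]):
    """Per-gene (n_exons, n_introns) plus the family mean exon count (2 dp)."""
    if not genes:
        raise ValueError("structure_stats needs at least one gene")
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "n_exons": [g.n_exons for g in genes],
            "n_introns": [g.n_introns for g in genes],
            "is_family_member": [g.is_family_member for g in genes],
        }
    )
    fam = df[df.is_family_member] if df.is_family_member.any() else df
    mean_exons = round(float(fam.n_exons.mean()), 2)
    return df, mean_exons


# ---------------------------------------------------------------------------
# cluster detection


def _intergenic_gap(prev: GeneModel, nxt: GeneModel) -> int:
    return nxt.start - prev.end - 1


def _intervening_count(genes: Sequence[GeneModel], prev: GeneModel, nxt: GeneModel) -> int:
    # non-family genes whose spans lie strictly between the two family genes
    return sum(
        1
        for g in genes
        if g.chrom == prev.chrom
        and not g.is_family_member
        and g.start > prev.end
        and g.end < nxt.start
    )


def detect_clusters(genes: Sequence[GeneModel], rule: ClusterRule = ClusterRule()) -> list:
    """Maximal runs of rule-linked neighbouring family genes (>= 2 members)."""
    order = [(g.chrom, g.start, g.gene_id) for g in genes]
    if order != sorted(order):
        raise ValueError("genes must be sorted by (chrom, start); refusing to sort silently")
    clusters = []
    run: list = []

    def flush(run):
        if len(run) >= 2:
            clusters.append(run[:])

    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        chrom_genes = by_chrom[chrom]
        fam = [g for g in chrom_genes if g.is_family_member]
        run = []
        for g in fam:
            if not run:
                run = [g]
                continue
            prev = run[-1]
            gap = _intergenic_gap(prev, g)
            linked = (
                gap < rule.max_gap_bp
                and _intervening_count(chrom_genes, prev, g)
                <= rule.max_intervening_genes
            )
            if linked:
                run.append(g)
            else:
                flush(run)
                run = [g]
        flush(run)
    out = []
    for i, run in enumerate(clusters, start=1):
        out.append(
            GeneCluster(
                cluster_id=f"CLU{i}",
                chrom=run[0].chrom,
                members=tuple(g.gene_id for g in run),
                span_bp=run[-1].end - run[0].start + 1,
            )
        )
    return out


def chromosome_distribution(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-chromosome family gene counts and percentages (1 dp)."""
    fam = [g for g in genes if g.is_family_member]
    counts: dict = {}
    for g in fam:
        counts[g.chrom] = counts.get(g.chrom, 0) + 1
    total = sum(counts.values())
    rows = [
        {"chrom": c, "n_genes": n, "pct": round(100.0 * n / total, 1) if total else 0.0}
        for c, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "n_genes", "pct"])


# ---------------------------------------------------------------------------
# export


def clusters_to_bed(clusters: Sequence[GeneCluster], genes: Sequence[GeneModel]) -> str:
    """Clusters as BED text (0-based half-open)."""
    pos = {g.gene_id: g for g in genes}
    lines = []
    for c in clusters:
        start = pos[c.members[0]].start - 1
        end = pos[c.members[-1]].end
        lines.append(f"{c.chrom}\t{start}\t{end}\t{c.cluster_id}\t{len(c.members)}\t.")
    return "\n".join(lines) + ("\n" if lines else "")


def clusters_to_table(clusters: Sequence[GeneCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "chrom": c.chrom,
                "n_members": len(c.members),
                "members": ";".join(c.members),
                "span_bp": c.span_bp,
            }
            for c in clusters
        ],
        columns=["cluster_id", "chrom", "n_members", "members", "span_bp"],
    )
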