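"""Seeded generators for every input the survey pipeline consumes.

Each generator is a deterministic function of (parameters, seed) and
returns the generated records together with a machine-readable truth
table, so every pipeline stage can be tested closed-loop without any
external download: at zero noise, a stage applied to its generator's
output must reproduce the truth table exactly.

Protein backgrounds are drawn from an alphabet without C, H and W.  That
is the rejection guarantee in closed form: every heptapeptide variant
starts with W and every zinc-finger pattern needs C and H, so no spurious
domain can arise outside the planted segments, and planted fingers are
always the leftmost match for their heptapeptide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .evolution import syn_site_fraction, _STOPS, _translate_codon
from .expression import COMPARISONS, QpcrTable, signed_fc, load_table1
from .genome_context import ClusterRule, GeneModel
from .phylo import ReferencePanel
from .promoter_cares import IUPAC, load_care_motifs, revcomp

__all__ = [
    "PROTEIN_BG_ALPHABET",
    "SyntheticProteome",
    "SyntheticGenome",
    "SyntheticOrthologs",
    "SyntheticQpcr",
    "SyntheticPromoters",
    "make_proteome",
    "make_reference_panel",
    "make_genome",
    "make_ortholog_pairs",
    "make_qpcr",
    "design_from_table1",
    "make_promoters",
]

#: 20 canonical residues minus C, H, W (see module docstring).
PROTEIN_BG_ALPHABET = "ADEFGIKLMNPQRSTVY"

PROTEIN_CLASSES = (
    "group1", "2a", "2b", "2c", "2d", "2e",
    "group3", "ungrouped", "incomplete", "duplicate",
)
SUBGROUPS = ("2a", "2b", "2c", "2d", "2e")

#: RNG stream anchor for subgroup centroid flanks; fixed so panels and
#: queries generated in separate calls share the same centroids.
CENTROID_SEED = 20170323
_CENTROID_TAGS = ("2a", "2b", "2c", "2d", "2e", "group1", "group3")
_FLANK_LEN = 40


def _bg(rng: np.random.Generator, n: int, alphabet: str = PROTEIN_BG_ALPHABET) -> str:
    return "".join(rng.choice(list(alphabet), size=n)) if n else ""


def subgroup_centroid(tag: str, length: int = _FLANK_LEN) -> str:
    """Deterministic flanking-sequence centroid for a class tag."""
    idx = _CENTROID_TAGS.index(tag)
    rng = np.random.default_rng([CENTROID_SEED, idx])
    return _bg(rng, length)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in PROTEIN_BG_ALPHABET if a != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _finger(rng: np.random.Generator, ftype: str, g1: int, g2: int) -> str:
    last = "H" if ftype == "C2H2" else "C"
    return "C" + _bg(rng, g1) + "C" + _bg(rng, g2) + "H" + _bg(rng, 1) + last


@dataclass
class SyntheticProteome:
    records: list  # family_scan.ProteinRecord
    truth: pd.DataFrame
    seed: int


def make_proteome(
    n_per_class: Mapping[str, int],
    seed: int = 1,
    flank_mut_rate: float = 0.02,
) -> SyntheticProteome:
    """Proteins carrying each class's planted domain architecture.

    Classes: ``group1`` (two C2H2 domains), ``2a``..``2e`` (one C2H2
    domain with a subgroup-specific flanking centroid), ``group3`` (one
    C2HC domain), ``ungrouped`` (mixed C2H2+C2HC architecture),
    ``incomplete`` (heptapeptide with no finger), ``duplicate`` (exact
    copy of an earlier record under a new id).  The truth table records
    every planted feature with 1-based coordinates.
    """
    from .family_scan import ProteinRecord

    bad = set(n_per_class) - set(PROTEIN_CLASSES)
    if bad:
        raise ValueError(f"unknown protein classes: {sorted(bad)}")
    if any(v < 0 for v in n_per_class.values()):
        raise ValueError("class counts must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    rows = []
    originals = []  # candidates for duplication
    counter = 0

    def emit(seq, cls, group, subgroup, heptas, fingers, domain_seq, dup_of=""):
        nonlocal counter
        counter += 1
        pid = f"SYN{counter:04d}"
        records.append(ProteinRecord(id=pid, sequence=seq, source=f"synthetic:{cls}"))
        rows.append(
            {
                "id": pid,
                "protein_class": cls,
                "group": group,
                "subgroup": subgroup,
                "hepta_variants": ";".join(h[0] for h in heptas),
                "hepta_starts": ";".join(str(h[1]) for h in heptas),
                "finger_types": ";".join(f[0] for f in fingers),
                "finger_starts": ";".join(str(f[1]) for f in fingers),
                "domain_seq": domain_seq,
                "duplicate_of": dup_of,
                "length": len(seq),
            }
        )
        return pid

    def build_domain(hepta, spacer_len, ftype, g1, g2, flank):
        """hepta + spacer + finger + flank; returns (segment, rel coords)."""
        spacer = _bg(rng, spacer_len)
        fingerseq = _finger(rng, ftype, g1, g2)
        seg = hepta + spacer + fingerseq + flank
        finger_rel = len(hepta) + spacer_len + 1  # 1-based within segment
        return seg, finger_rel

    order = [c for c in PROTEIN_CLASSES if c != "duplicate"]
    for cls in order:
        for _ in range(int(n_per_class.get(cls, 0))):
            pre = _bg(rng, int(rng.integers(20, 50)))
            post = _bg(rng, int(rng.integers(10, 40)))
            if cls == "group1":
                flank = _mutate(rng, subgroup_centroid("group1"), flank_mut_rate)
                seg1, f1 = build_domain("WRKYGQK", 12, "C2H2", 4, 22, "")
                mid = _bg(rng, 25)
                seg2, f2 = build_domain("WRKYGQK", 12, "C2H2", 4, 23, flank)
                seq = pre + seg1 + mid + seg2 + post
                h1 = len(pre) + 1
                h2 = len(pre) + len(seg1) + len(mid) + 1
                heptas = [("WRKYGQK", h1), ("WRKYGQK", h2)]
                fingers = [("C2H2", h1 - 1 + f1), ("C2H2", h2 - 1 + f2)]
                emit(seq, cls, "1", "none", heptas, fingers, seg2)
            elif cls in SUBGROUPS:
                if cls == "2c":
                    hepta = ["WRKYGQK", "WRKYGKK", "WRKYGEK"][int(rng.integers(3))]
                else:
                    hepta = "WRKYGQK"
                flank = _mutate(rng, subgroup_centroid(cls), flank_mut_rate)
                seg, f = build_domain(hepta, 10, "C2H2", 5, 23, flank)
                seq = pre + seg + post
                h = len(pre) + 1
                emit(seq, cls, "2", cls, [(hepta, h)], [("C2H2", h - 1 + f)], seg)
            elif cls == "group3":
                flank = _mutate(rng, subgroup_centroid("group3"), flank_mut_rate)
                seg, f = build_domain("WRKYGQK", 8, "C2HC", 7, 23, flank)
                seq = pre + seg + post
                h = len(pre) + 1
                emit(seq, cls, "3", "none", [("WRKYGQK", h)], [("C2HC", h - 1 + f)], seg)
            elif cls == "ungrouped":
                seg1, f1 = build_domain("WKKYEDK", 10, "C2H2", 5, 23, "")
                mid = _bg(rng, 25)
                seg2, f2 = build_domain("WKKYEDK", 8, "C2HC", 7, 23, "")
                seq = pre + seg1 + mid + seg2 + post
                h1 = len(pre) + 1
                h2 = len(pre) + len(seg1) + len(mid) + 1
                emit(
                    seq, cls, "ungrouped", "none",
                    [("WKKYEDK", h1), ("WKKYEDK", h2)],
                    [("C2H2", h1 - 1 + f1), ("C2HC", h2 - 1 + f2)],
                    seg1,
                )
            elif cls == "incomplete":
                hepta = "WRKYGQK"
                seq = pre + hepta + _bg(rng, 70) + post
                emit(seq, cls, "ungrouped", "none", [(hepta, len(pre) + 1)], [], "")
            originals.append(len(records) - 1)
    for _ in range(int(n_per_class.get("duplicate", 0))):
        if not originals:
            raise ValueError("cannot plant duplicates without any original record")
        src_idx = int(rng.integers(len(originals)))
        src = records[originals[src_idx]]
        src_row = rows[originals[src_idx]]
        emit(
            src.sequence, "duplicate", src_row["group"], src_row["subgroup"],
            list(zip(src_row["hepta_variants"].split(";") if src_row["hepta_variants"] else [],
                     map(int, src_row["hepta_starts"].split(";")) if src_row["hepta_starts"] else [])),
            list(zip(src_row["finger_types"].split(";") if src_row["finger_types"] else [],
                     map(int, src_row["finger_starts"].split(";")) if src_row["finger_starts"] else [])),
            src_row["domain_seq"],
            dup_of=src.id,
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "id", "protein_class", "group", "subgroup", "hepta_variants",
            "hepta_starts", "finger_types", "finger_starts", "domain_seq",
            "duplicate_of", "length",
        ],
    )
    return SyntheticProteome(records=records, truth=truth, seed=seed)


def make_reference_panel(
    seed: int = 1,
    n_per_tag: int = 3,
    tags: Sequence[str] = SUBGROUPS,
    flank_mut_rate: float = 0.02,
) -> ReferencePanel:
    """Aligned reference panel of subgroup domain sequences."""
    prot = make_proteome({t: n_per_tag for t in tags}, seed=seed,
                         flank_mut_rate=flank_mut_rate)
    seqs = {}
    tag_map = {}
    for _, row in prot.truth.iterrows():
        label = f"{row['subgroup']}_{row['id']}"
        seqs[label] = row["domain_seq"]
        tag_map[label] = row["subgroup"]
    return ReferencePanel(sequences=seqs, tags=tag_map)


# ---------------------------------------------------------------------------
# genome layouts


@dataclass
class SyntheticGenome:
    genes: list  # genome_context.GeneModel, sorted (chrom, start)
    sequences: Optional[dict]  # chrom -> str, when requested
    truth: pd.DataFrame
    seed: int

    def gff3(self) -> str:
        import io
        from .genome_context import write_gff3

        buf = io.StringIO()
        write_gff3(self.genes, buf)
        return buf.getvalue()


def _make_gene(rng, gene_id, chrom, start, strand=None):
    n_exons = int(rng.integers(1, 6))
    exon_lens = rng.integers(100, 400, size=n_exons)
    intron_lens = rng.integers(50, 300, size=max(0, n_exons - 1))
    exons = []
    cur = start
    for i in range(n_exons):
        exons.append((cur, cur + int(exon_lens[i]) - 1))
        cur = exons[-1][1] + 1
        if i < n_exons - 1:
            cur += int(intron_lens[i])
    end = exons[-1][1]
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand or ("+" if rng.random() < 0.5 else "-"),
        exons=exons,
        cds=list(exons),
    )


def make_genome(
    n_chroms: int = 3,
    n_genes: int = 100,
    n_family: int = 20,
    cluster_spec: Sequence[int] = (2, 3),
    seed: int = 1,
    rule: ClusterRule = ClusterRule(),
    with_sequence: bool = False,
) -> SyntheticGenome:
    """Gene layout with planted family clusters and isolated family genes.

    Planted clusters satisfy the cluster rule strictly (small gaps, few
    intervening non-family genes); family genes outside clusters are
    separated from any other family gene by at least twice the rule's
    maximum gap, so they can never link.
    """
    if n_family > n_genes:
        raise ValueError("n_family cannot exceed n_genes")
    if any(k < 2 for k in cluster_spec):
        raise ValueError("cluster sizes must be >= 2")
    n_clustered = sum(cluster_spec)
    if n_clustered > n_family:
        raise ValueError("cluster_spec plants more family genes than n_family")
    rng = np.random.default_rng(seed)
    n_singletons = n_family - n_clustered
    # non-family budget: intervening genes inside clusters come out of it
    n_nonfam = n_genes - n_family
    max_inter = min(3, rule.max_intervening_genes)

    units = []  # ("cluster", idx, size) | ("singleton",) assigned round-robin
    for ci, size in enumerate(cluster_spec):
        units.append(("cluster", ci, size))
    for _ in range(n_singletons):
        units.append(("singleton", None, 1))

    genes = []
    rows = []
    counter = [0]
    nonfam_used = [0]

    def next_id(fam):
        counter[0] += 1
        return ("F" if fam else "N") + f"{counter[0]:04d}"

    chrom_cursor = {f"Chr{i+1}": int(rng.integers(1_000, 50_000)) for i in range(n_chroms)}
    chrom_names = sorted(chrom_cursor)

    def place(chrom, fam, cluster_id=""):
        gid = next_id(fam)
        g = _make_gene(rng, gid, chrom, chrom_cursor[chrom])
        chrom_cursor[chrom] = g.end + 1
        g.is_family_member = fam
        genes.append(g)
        rows.append(
            {
                "gene_id": gid, "chrom": chrom, "start": g.start, "end": g.end,
                "strand": g.strand, "is_family": fam, "cluster_id": cluster_id,
                "n_exons": g.n_exons,
            }
        )
        return g

    for ui, unit in enumerate(units):
        chrom = chrom_names[ui % n_chroms]
        kind, ci, size = unit
        # isolation gap before any family unit
        chrom_cursor[chrom] += 2 * rule.max_gap_bp + int(rng.integers(0, 100_000))
        if kind == "singleton":
            place(chrom, True)
            continue
        cluster_id = f"PLANT{ci+1}"
        for mi in range(size):
            place(chrom, True, cluster_id)
            if mi < size - 1:
                k = int(rng.integers(0, max_inter + 1))
                k = min(k, n_nonfam - nonfam_used[0])
                gap_total = int(rng.integers(5_000, rule.max_gap_bp - 10_000))
                inner = gap_total // (k + 1)
                for _ in range(k):
                    chrom_cursor[chrom] += max(200, inner - 3_000)
                    g = place(chrom, False)
                    nonfam_used[0] += 1
                chrom_cursor[chrom] += max(200, inner - 3_000)
    # leftover non-family genes: appended past a final isolation gap
    for i in range(n_nonfam - nonfam_used[0]):
        chrom = chrom_names[i % n_chroms]
        chrom_cursor[chrom] += 2 * rule.max_gap_bp if i < n_chroms else int(
            rng.integers(1_000, 20_000)
        )
        place(chrom, False)

    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    truth = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    sequences = None
    if with_sequence:
        sequences = {}
        for chrom in chrom_names:
            length = max(
                [g.end for g in genes if g.chrom == chrom] + [2_000]
            ) + 2_000
            arr = rng.integers(0, 4, size=length)
            sequences[chrom] = "".join("ACGT"[i] for i in arr)
    return SyntheticGenome(genes=genes, sequences=sequences, truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# ortholog codon pairs


@dataclass
class SyntheticOrthologs:
    pairs: list  # (id_a, prot_a, cds_a, id_b, prot_b, cds_b)
    truth: pd.DataFrame
    seed: int


_NONSTOP_CODONS = sorted(
    c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
    if c not in _STOPS
)


def _proportion(target_rate: float) -> float:
    """Invert the Jukes–Cantor correction: rate -> difference proportion."""
    return 0.75 * (1.0 - math.exp(-4.0 * target_rate / 3.0))


def make_ortholog_pairs(
    n_pairs: int = 20,
    n_codons: int = 500,
    target_ks: float = 0.25,
    target_ka: float = 0.05,
    seed: int = 1,
) -> SyntheticOrthologs:
    """Codon pairs with substitutions planted at NG86 site-class densities.

    Synonymous and nonsynonymous single-nucleotide substitutions are
    planted in distinct codons at proportions matching the Jukes–Cantor
    inverse of the targets, so the NG86 estimator recovers ``target_ks``
    and ``target_ka`` in expectation.  Defaults emulate a legume ortholog
    set under purifying selection (Ks around 0.25, Ka/Ks = 0.2).
    """
    if target_ks < 0 or target_ka < 0:
        raise ValueError("targets must be >= 0")
    if n_codons < 50:
        raise ValueError("n_codons must be >= 50")
    rng = np.random.default_rng(seed)
    pairs = []
    rows = []
    for pi in range(n_pairs):
        codons = [
            _NONSTOP_CODONS[int(i)]
            for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
        ]
        S = sum(syn_site_fraction(c) for c in codons)
        N = 3 * n_codons - S
        n_syn = int(round(_proportion(target_ks) * S))
        n_nonsyn = int(round(_proportion(target_ka) * N))
        derived = codons[:]
        order = rng.permutation(n_codons)
        used = set()
        planted_syn = 0
        for idx in order:
            if planted_syn == n_syn:
                break
            c = codons[idx]
            opts = []
            for pos in range(3):
                for nuc in "ACGT":
                    if nuc == c[pos]:
                        continue
                    alt = c[:pos] + nuc + c[pos + 1 :]
                    if alt not in _STOPS and _translate_codon(alt) == _translate_codon(c):
                        opts.append(alt)
            if not opts:
                continue
            derived[idx] = opts[int(rng.integers(len(opts)))]
            used.add(int(idx))
            planted_syn += 1
        planted_nonsyn = 0
        for idx in order[::-1]:
            if planted_nonsyn == n_nonsyn:
                break
            if int(idx) in used:
                continue
            c = codons[idx]
            opts = []
            for pos in range(3):
                for nuc in "ACGT":
                    if nuc == c[pos]:
                        continue
                    alt = c[:pos] + nuc + c[pos + 1 :]
                    if alt not in _STOPS and _translate_codon(alt) != _translate_codon(c):
                        opts.append(alt)
            if not opts:
                continue
            derived[idx] = opts[int(rng.integers(len(opts)))]
            used.add(int(idx))
            planted_nonsyn += 1
        cds_a = "".join(codons)
        cds_b = "".join(derived)
        prot_a = str(Seq(cds_a).translate())
        prot_b = str(Seq(cds_b).translate())
        pid = f"PAIR{pi+1:03d}"
        pairs.append((f"{pid}_a", prot_a, cds_a, f"{pid}_b", prot_b, cds_b))
        rows.append(
            {
                "pair_id": pid,
                "n_codons": n_codons,
                "target_ks": target_ks,
                "target_ka": target_ka,
                "n_syn_planted": planted_syn,
                "n_nonsyn_planted": planted_nonsyn,
                "S_ancestor": round(S, 4),
                "N_ancestor": round(N, 4),
            }
        )
    return SyntheticOrthologs(pairs=pairs, truth=pd.DataFrame(rows), seed=seed)


# ---------------------------------------------------------------------------
# qPCR CT tables


@dataclass
class SyntheticQpcr:
    table: QpcrTable
    truth: pd.DataFrame  # planted signed FC per gene and comparison
    seed: int


def design_from_table1() -> pd.DataFrame:
    """Per-sample expression ratios reproducing the packaged fold-change table.

    LOI is the unit baseline; absent cells mean "no change" (ratio carried
    over from the comparison's control sample).
    """
    t1 = load_table1()
    rows = []
    for _, r in t1.iterrows():
        loi = 1.0
        fc_lt = r["fc_LOI_LTD"]
        fc_nn = r["fc_LOI_NOI"]
        fc_nt = r["fc_NOI_NTD"]
        to_ratio = lambda v: 1.0 if pd.isna(v) else (v if v >= 1 else -1.0 / v)
        ltd = loi * to_ratio(fc_lt)
        noi = loi * to_ratio(fc_nn)
        ntd = noi * to_ratio(fc_nt)
        rows.append({"gene": r["gene"], "LOI": loi, "LTD": ltd, "NOI": noi, "NTD": ntd})
    return pd.DataFrame(rows).set_index("gene")


def make_qpcr(
    design: Optional[pd.DataFrame] = None,
    noise_sd: float = 0.0,
    n_reps: int = 3,
    seed: int = 1,
    reference_gene: str = "Skip16",
    base_ct: float = 24.0,
    reference_ct: float = 18.0,
) -> SyntheticQpcr:
    """CT replicate table encoding planted per-sample expression ratios.

    ``design`` is genes x samples (LOI, LTD, NOI, NTD) of positive
    expression ratios relative to an arbitrary unit baseline; target CTs
    are offset by -log2(ratio) and Gaussian noise of ``noise_sd`` cycles
    is added per replicate.  Defaults replay the packaged drought
    fold-change table at zero noise.
    """
    if n_reps < 3:
        raise ValueError("n_reps must be >= 3")
    if design is None:
        design = design_from_table1()
    if (design <= 0).any().any():
        raise ValueError("design ratios must be positive")
    rng = np.random.default_rng(seed)
    recs = []
    for sample in SAMPLES_ORDER:
        for _ in range(n_reps):
            recs.append(
                {
                    "sample": sample,
                    "gene": reference_gene,
                    "ct": reference_ct + rng.normal(0, noise_sd) if noise_sd else reference_ct,
                }
            )
        for gene, row in design.iterrows():
            for _ in range(n_reps):
                ct = base_ct - math.log2(float(row[sample]))
                if noise_sd:
                    ct += rng.normal(0, noise_sd)
                recs.append({"sample": sample, "gene": gene, "ct": ct})
    table = QpcrTable(data=pd.DataFrame(recs), reference_gene=reference_gene)
    rows = []
    for gene, row in design.iterrows():
        for name, treatment, control in COMPARISONS:
            ratio = float(row[treatment]) / float(row[control])
            rows.append(
                {
                    "gene": gene,
                    "comparison": name,
                    "planted_ratio": ratio,
                    "planted_signed_fc": signed_fc(ratio),
                }
            )
    return SyntheticQpcr(table=table, truth=pd.DataFrame(rows), seed=seed)


SAMPLES_ORDER = ("LOI", "LTD", "NOI", "NTD")


# ---------------------------------------------------------------------------
# promoters


@dataclass
class SyntheticPromoters:
    promoters: dict  # id -> sequence
    truth: pd.DataFrame
    seed: int


def make_promoters(
    n: int = 10,
    length: int = 1500,
    plantings: Sequence[tuple] = (),
    seed: int = 1,
    alphabet: str = "ACGT",
    motif_consensi: Optional[Mapping[str, str]] = None,
) -> SyntheticPromoters:
    """Random promoters with planted cis-element instances.

    ``plantings`` holds ``(promoter_index, motif_name, offset_1based,
    strand)`` tuples; degenerate consensus positions are instantiated
    randomly and minus-strand plantings insert the reverse complement.
    Overlapping plantings in one promoter raise.  Restricting
    ``alphabet`` lets callers build motif-free backgrounds for exact
    closed-loop truth checks.
    """
    if motif_consensi is None:
        motif_consensi = {m.name: m.consensus for m in load_care_motifs()}
    rng = np.random.default_rng(seed)
    seqs = [
        "".join(rng.choice(list(alphabet), size=length)) for _ in range(n)
    ]
    occupied: dict = {i: [] for i in range(n)}
    rows = []
    for idx, motif_name, offset, strand in plantings:
        if not 0 <= idx < n:
            raise ValueError(f"promoter index {idx} out of range")
        consensus = motif_consensi[motif_name]
        inst = "".join(
            IUPAC[c][int(rng.integers(len(IUPAC[c])))] for c in consensus.upper()
        )
        if strand == "-":
            inst_fwd = revcomp(inst)
        else:
            inst_fwd = inst
        start0 = offset - 1
        end0 = start0 + len(inst_fwd)
        if start0 < 0 or end0 > length:
            raise ValueError(f"planting {motif_name}@{offset} does not fit")
        for s, e in occupied[idx]:
            if start0 < e and s < end0:
                raise ValueError(
                    f"overlapping plantings in promoter {idx} at offset {offset}"
                )
        occupied[idx].append((start0, end0))
        seqs[idx] = seqs[idx][:start0] + inst_fwd + seqs[idx][end0:]
        rows.append(
            {
                "promoter_id": f"P{idx+1}",
                "motif": motif_name,
                "offset": offset,
                "strand": strand,
                "planted_seq": inst,
            }
        )
    promoters = {f"P{i+1}": s for i, s in enumerate(seqs)}
    truth = pd.DataFrame(
        rows, columns=["promoter_id", "motif", "offset", "strand", "planted_seq"]
    )
    return SyntheticPromoters(promoters=promoters, truth=truth, seed=seed)
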