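"""Locate WRKY domains in protein sequences and classify family members.

A WRKY domain is defined by two features: a near-invariant heptapeptide
(canonically ``WRKYGQK``, with a handful of natural variants) and a
zinc-finger motif a short distance downstream.  Two finger architectures
occur in the family::

    C2H2 :  C x(4-5) C x(22-23) H x H
    C2HC :  C x7     C x23      H x C

Group 1 proteins carry two complete domains with C2H2 fingers, group 2 one
C2H2 domain, group 3 one C2HC domain; anything else (heptapeptide without a
classifiable finger, mixed finger types, no domain at all) is left
ungrouped with an explanatory note.

Identification here is deterministic pattern matching over an exact,
user-extensible heptapeptide set; no probabilistic profile search is
performed (the E-value threshold in :class:`ScanConfig` is retained for
interoperability with external profile pipelines but unused locally).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_HEPTAPEPTIDES",
    "ProteinRecord",
    "ZincFingerMotif",
    "WrkyDomainHit",
    "FamilyClassification",
    "ProteinFeatures",
    "ScanConfig",
    "find_heptapeptides",
    "find_zinc_finger",
    "scan_protein",
    "classify_protein",
    "dedupe_and_filter",
    "protein_features",
    "family_table",
    "hits_to_json",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_ALPHABET = AMINO_ACIDS | {"X"}

#: Heptapeptide variants observed in the family. ``WKKYCEDK`` is an
#: eight-residue variant carried by the two unclassifiable members and is
#: treated literally as an 8-mer.
DEFAULT_HEPTAPEPTIDES = (
    "WRKYGQK",
    "WRKYGKK",
    "WRKYGEK",
    "WKKYEDK",
    "WKKYCEDK",
)

# C2H2 spacings enumerated in preference order: smaller gap1, then smaller
# gap2; the single C2HC spacing ranks after any C2H2 match at the same Cys.
_FINGER_PATTERNS = (
    ("C2H2", 4, 22, "H"),
    ("C2H2", 4, 23, "H"),
    ("C2H2", 5, 22, "H"),
    ("C2H2", 5, 23, "H"),
    ("C2HC", 7, 23, "C"),
)

# Average (isotope-abundance weighted) residue masses, Da.
RESIDUE_MASSES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.0153

#: Bjellqvist-style pKa set as used by common pI web calculators.
DEFAULT_PKA = {
    "n_term": 7.5,
    "c_term": 3.55,
    "C": 9.0,
    "D": 4.05,
    "E": 4.45,
    "H": 5.98,
    "K": 10.0,
    "R": 12.0,
    "Y": 10.0,
}


class SequenceError(ValueError):
    """Raised for empty or non-alphabet protein sequences."""


class FeatureError(ValueError):
    """Raised when physico-chemical features cannot be computed."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    source: str = ""

    def validate(self) -> "ProteinRecord":
        if not self.sequence:
            raise SequenceError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - EXTENDED_ALPHABET
        if bad:
            raise SequenceError(
                f"{self.id}: non-alphabet character(s) {sorted(bad)}"
            )
        return self


@dataclass(frozen=True)
class ZincFingerMotif:
    """A matched zinc-finger pattern; ``start`` is the 1-based first Cys."""

    type: str  # "C2H2" | "C2HC"
    spacings: tuple  # (gap1, gap2, gap3)
    start: int

    def __post_init__(self):
        g1, g2, g3 = self.spacings
        if self.type == "C2H2":
            ok = g1 in (4, 5) and g2 in (22, 23) and g3 == 1
        elif self.type == "C2HC":
            ok = (g1, g2, g3) == (7, 23, 1)
        else:
            ok = False
        if not ok:
            raise ValueError(f"invalid finger {self.type} spacings {self.spacings}")

    @property
    def end(self) -> int:
        """1-based inclusive index of the last coordinating residue."""
        g1, g2, g3 = self.spacings
        return self.start + 1 + g1 + 1 + g2 + 1 + g3


@dataclass(frozen=True)
class WrkyDomainHit:
    heptapeptide: str
    hepta_start: int  # 1-based
    zinc_finger: Optional[ZincFingerMotif] = None
    complete: bool = False

    @property
    def hepta_end(self) -> int:
        return self.hepta_start + len(self.heptapeptide) - 1


@dataclass(frozen=True)
class FamilyClassification:
    group: str  # "1" | "2" | "3" | "ungrouped"
    subgroup: str = "none"  # "2a".."2e" | "none"
    n_domains: int = 0
    notes: str = ""

    def __post_init__(self):
        if self.subgroup != "none" and self.group != "2":
            raise ValueError("subgroups exist only within group 2")


@dataclass(frozen=True)
class ProteinFeatures:
    length: int
    molecular_weight: float  # kDa
    isoelectric_point: float
    orf_length: int  # nt, coding + stop


@dataclass
class ScanConfig:
    allowed_heptapeptides: Sequence[str] = DEFAULT_HEPTAPEPTIDES
    finger_search_window: int = 60
    evalue_threshold: float = 1e-5  # placeholder for external profile search
    require_complete_domain: bool = True
    pka_table: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))

    def __post_init__(self):
        if self.finger_search_window < 1:
            raise ValueError("finger_search_window must be >= 1")
        if not self.allowed_heptapeptides:
            raise ValueError("allowed_heptapeptides must be non-empty")


# ---------------------------------------------------------------------------
# domain finding


def find_heptapeptides(protein: ProteinRecord, cfg: ScanConfig) -> list:
    """All exact occurrences of the allowed heptapeptide variants.

    Returns ``[(variant, 1-based start), ...]`` sorted by position.
    Overlapping occurrences of different variants are all reported.
    """
    protein.validate()
    seq = protein.sequence
    out = []
    for i in range(len(seq)):
        for variant in cfg.allowed_heptapeptides:
            if seq.startswith(variant, i):
                out.append((variant, i + 1))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def find_zinc_finger(
    protein: ProteinRecord, from_index: int, cfg: ScanConfig
) -> Optional[ZincFingerMotif]:
    """First zinc finger whose leading Cys lies in the search window.

    The window limits only the position of the first Cys: it may sit at
    most ``finger_search_window - 1`` residues after ``from_index``
    (1-based).  At a given Cys, smaller gap1 is preferred, then smaller
    gap2, and C2H2 beats C2HC.
    """
    seq = protein.sequence
    if not 1 <= from_index <= len(seq):
        return None
    last_c1 = min(len(seq), from_index + cfg.finger_search_window - 1)
    for c1 in range(from_index - 1, last_c1):  # 0-based
        if seq[c1] != "C":
            continue
        for ftype, g1, g2, last_res in _FINGER_PATTERNS:
            c2 = c1 + 1 + g1
            h1 = c2 + 1 + g2
            last = h1 + 2
            if last >= len(seq):
                continue
            if seq[c2] == "C" and seq[h1] == "H" and seq[last] == last_res:
                return ZincFingerMotif(type=ftype, spacings=(g1, g2, 1), start=c1 + 1)
    return None


def scan_protein(protein: ProteinRecord, cfg: ScanConfig) -> list:
    """One :class:`WrkyDomainHit` per heptapeptide occurrence."""
    hits = []
    for variant, start in find_heptapeptides(protein, cfg):
        hepta_end = start + len(variant) - 1
        finger = None
        if hepta_end < len(protein.sequence):
            finger = find_zinc_finger(protein, hepta_end + 1, cfg)
        hits.append(
            WrkyDomainHit(
                heptapeptide=variant,
                hepta_start=start,
                zinc_finger=finger,
                complete=finger is not None,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# classification


def classify_protein(hits: Sequence[WrkyDomainHit]) -> FamilyClassification:
    """Group assignment from a protein's position-sorted domain hits.

    Two complete C2H2 domains -> group 1; one complete C2H2 -> group 2
    (subgroup resolution is a separate, phylogeny-based step); one complete
    C2HC -> group 3.  Everything else is ungrouped with a note.
    """
    complete = [h for h in hits if h.complete]
    types = [h.zinc_finger.type for h in complete]
    if len(complete) == 2 and types == ["C2H2", "C2H2"]:
        return FamilyClassification(group="1", n_domains=2)
    if len(complete) == 1 and types == ["C2H2"]:
        return FamilyClassification(group="2", n_domains=1)
    if len(complete) == 1 and types == ["C2HC"]:
        return FamilyClassification(group="3", n_domains=1)
    if not hits:
        note = "no WRKY domain evidence"
    elif not complete:
        note = "heptapeptide(s) without classifiable zinc finger"
    else:
        note = (
            f"unassignable domain architecture: {len(complete)} complete "
            f"domain(s) with finger types {types}"
        )
    return FamilyClassification(group="ungrouped", n_domains=len(hits), notes=note)


def dedupe_and_filter(
    proteins: Sequence[ProteinRecord],
    hits_per_protein: Sequence[Sequence[WrkyDomainHit]],
    cfg: ScanConfig,
    gene_models: Optional[Mapping[str, object]] = None,
    rename_prefix: str = "WRKY",
):
    """Collapse exact duplicates, drop incomplete records, rename survivors.

    Duplicate sequences keep the lexicographically smallest id.  When
    ``cfg.require_complete_domain`` records without any complete domain are
    removed.  Survivors are renamed ``<prefix>1..N`` ordered by
    (chrom, start) when ``gene_models`` (id -> object with .chrom/.start)
    is given, else by input order.

    Returns ``(survivors, id_map)`` where survivors are renamed
    :class:`ProteinRecord` objects and ``id_map`` maps original id ->
    new id (dropped records are absent).
    """
    if len(proteins) != len(hits_per_protein):
        raise ValueError("hits_per_protein must align with proteins")
    by_seq: dict = {}
    hits_by_id = {}
    for rec, hits in zip(proteins, hits_per_protein):
        hits_by_id[rec.id] = hits
        cur = by_seq.get(rec.sequence)
        if cur is None or rec.id < cur.id:
            by_seq[rec.sequence] = rec
    kept = [r for r in proteins if by_seq[r.sequence].id == r.id]
    if cfg.require_complete_domain:
        kept = [r for r in kept if any(h.complete for h in hits_by_id[r.id])]
    if gene_models:
        def key(rec):
            gm = gene_models.get(rec.id)
            if gm is None:
                return ("~", 1 << 60, rec.id)  # unplaced genes sort last
            return (gm.chrom, gm.start, rec.id)
        kept = sorted(kept, key=key)
    survivors = []
    id_map = {}
    for i, rec in enumerate(kept, start=1):
        new_id = f"{rename_prefix}{i}"
        id_map[rec.id] = new_id
        survivors.append(ProteinRecord(id=new_id, sequence=rec.sequence,
                                       source=rec.source or rec.id))
    return survivors, id_map


# ---------------------------------------------------------------------------
# physico-chemical features


def _net_charge(seq: str, ph: float, pka: Mapping[str, float]) -> float:
    pos = 1.0 / (1.0 + 10 ** (ph - pka["n_term"]))
    for res in "KRH":
        if res in pka:
            pos += seq.count(res) / (1.0 + 10 ** (ph - pka[res]))
    neg = 1.0 / (1.0 + 10 ** (pka["c_term"] - ph))
    for res in "DECY":
        if res in pka:
            neg += seq.count(res) / (1.0 + 10 ** (pka[res] - ph))
    return pos - neg


def isoelectric_point(
    seq: str, pka: Mapping[str, float] = DEFAULT_PKA, tol: float = 1e-4
) -> float:
    """pH of zero net charge, solved by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = _net_charge(seq, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def protein_features(
    protein: ProteinRecord, pka: Mapping[str, float] = DEFAULT_PKA
) -> ProteinFeatures:
    """Length, average-mass MW (kDa), pI and implied ORF length (nt)."""
    protein.validate()
    seq = protein.sequence
    if "X" in seq:
        raise FeatureError(
            f"{protein.id}: cannot compute features with ambiguous residue X"
        )
    mw_da = sum(RESIDUE_MASSES[r] for r in seq) + WATER_MASS
    return ProteinFeatures(
        length=len(seq),
        molecular_weight=mw_da / 1000.0,
        isoelectric_point=isoelectric_point(seq, pka),
        orf_length=3 * (len(seq) + 1),
    )


# ---------------------------------------------------------------------------
# tabular / JSON output


def family_table(
    proteins: Sequence[ProteinRecord],
    hits_per_protein: Sequence[Sequence[WrkyDomainHit]],
    classifications: Sequence[FamilyClassification],
    with_features: bool = True,
) -> pd.DataFrame:
    rows = []
    for rec, hits, cls in zip(proteins, hits_per_protein, classifications):
        row = {
            "id": rec.id,
            "n_domains": sum(1 for h in hits if h.complete),
            "variants": ";".join(h.heptapeptide for h in hits),
            "finger_types": ";".join(
                h.zinc_finger.type for h in hits if h.zinc_finger
            ),
            "finger_spacings": ";".join(
                "-".join(map(str, h.zinc_finger.spacings))
                for h in hits if h.zinc_finger
            ),
            "group": cls.group,
            "subgroup": cls.subgroup,
            "notes": cls.notes,
        }
        if with_features:
            try:
                feats = protein_features(rec)
                row["mw_kda"] = round(feats.molecular_weight, 2)
                row["pi"] = round(feats.isoelectric_point, 2)
            except FeatureError:
                row["mw_kda"] = float("nan")
                row["pi"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def hits_to_json(
    proteins: Sequence[ProteinRecord],
    hits_per_protein: Sequence[Sequence[WrkyDomainHit]],
) -> str:
    """Full hit coordinates (1-based, inclusive) as a JSON string."""
    payload = {}
    for rec, hits in zip(proteins, hits_per_protein):
        payload[rec.id] = [
            {
                "heptapeptide": h.heptapeptide,
                "hepta_start": h.hepta_start,
                "hepta_end": h.hepta_end,
                "complete": h.complete,
                "zinc_finger": None
                if h.zinc_finger is None
                else {
                    "type": h.zinc_finger.type,
                    "spacings": list(h.zinc_finger.spacings),
                    "start": h.zinc_finger.start,
                    "end": h.zinc_finger.end,
                },
            }
            for h in hits
        ]
    return json.dumps(payload, indent=2, sort_keys=True)


def read_protein_fasta(path) -> list:
    """Protein FASTA -> validated records; trailing '*' stops stripped."""
    import warnings
    from Bio import SeqIO

    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        seq = str(sr.seq).upper()
        if "*" in seq:
            warnings.warn(f"{sr.id}: stop character(s) '*' stripped")
            seq = seq.replace("*", "")
        records.append(ProteinRecord(id=sr.id, sequence=seq).validate())
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise SequenceError("duplicate ids in FASTA input")
    return records
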