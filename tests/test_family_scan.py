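"""Domain scanning, group classification, and protein features."""

import numpy as np
import pytest

from wrkykit.family_scan import (
    DEFAULT_HEPTAPEPTIDES,
    DEFAULT_PKA,
    RESIDUE_MASSES,
    WATER_MASS,
    FeatureError,
    ProteinRecord,
    ScanConfig,
    SequenceError,
    WrkyDomainHit,
    ZincFingerMotif,
    classify_protein,
    dedupe_and_filter,
    find_heptapeptides,
    find_zinc_finger,
    protein_features,
    scan_protein,
    _net_charge,
)
from wrkykit.synthetic_data import PROTEIN_BG_ALPHABET, make_proteome

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# independent oracles


def hepta_oracle(seq, variants):
    """Check every 7-mer and 8-mer window against the allowed set."""
    out = []
    for i in range(len(seq)):
        for w in (7, 8):
            window = seq[i : i + w]
            if len(window) == w and window in variants:
                out.append((window, i + 1))
    return sorted(out, key=lambda t: (t[1], t[0]))


def finger_oracle(seq, from_index, window):
    """Enumerate all (c1, c2, h1, last) index quadruples for both spacings."""
    prefs = [("C2H2", 4, 22), ("C2H2", 4, 23), ("C2H2", 5, 22), ("C2H2", 5, 23),
             ("C2HC", 7, 23)]
    candidates = []
    for c1 in range(from_index - 1, min(len(seq), from_index - 1 + window)):
        for rank, (ftype, g1, g2) in enumerate(prefs):
            c2 = c1 + 1 + g1
            h1 = c2 + 1 + g2
            last = h1 + 2
            if last >= len(seq):
                continue
            want = "H" if ftype == "C2H2" else "C"
            if seq[c1] == "C" and seq[c2] == "C" and seq[h1] == "H" and seq[last] == want:
                candidates.append((c1, rank, ftype, g1, g2))
    if not candidates:
        return None
    c1, _, ftype, g1, g2 = min(candidates)
    return (ftype, g1, g2, c1 + 1)


# ---------------------------------------------------------------------------
# heptapeptide finding


def test_planted_exact_match(cfg):
    p = ProteinRecord(id="p", sequence="MAAWRKYGQKLVK")
    assert find_heptapeptides(p, cfg) == [("WRKYGQK", 4)]


def test_no_tryptophan_no_match(cfg):
    assert find_heptapeptides(ProteinRecord(id="p", sequence="MAAAAA"), cfg) == []


def test_empty_and_bad_alphabet_raise(cfg):
    with pytest.raises(SequenceError):
        find_heptapeptides(ProteinRecord(id="p", sequence=""), cfg)
    with pytest.raises(SequenceError):
        find_heptapeptides(ProteinRecord(id="p", sequence="MAB1"), cfg)


def test_scanner_matches_window_oracle_on_random_sequences(cfg, rng):
    variants = set(cfg.allowed_heptapeptides)
    for trial in range(250):
        n = int(rng.integers(20, 301))
        seq = "".join(rng.choice(list(AA), size=n))
        if trial % 3 == 0 and n > 30:  # plant a variant to exercise matches
            v = DEFAULT_HEPTAPEPTIDES[trial % len(DEFAULT_HEPTAPEPTIDES)]
            pos = int(rng.integers(0, n - len(v)))
            seq = seq[:pos] + v + seq[pos + len(v):]
        got = find_heptapeptides(ProteinRecord(id="r", sequence=seq), cfg)
        assert got == hepta_oracle(seq, variants)


# ---------------------------------------------------------------------------
# zinc fingers


def test_c2h2_pattern_forced(cfg):
    seq = "C" + "A" * 4 + "C" + "A" * 22 + "H" + "A" + "H"
    zf = find_zinc_finger(ProteinRecord(id="p", sequence=seq + "A"), 1, cfg)
    assert zf.type == "C2H2" and zf.spacings == (4, 22, 1) and zf.start == 1


def test_c2hc_pattern_forced(cfg):
    seq = "C" + "A" * 7 + "C" + "A" * 23 + "H" + "A" + "C"
    zf = find_zinc_finger(ProteinRecord(id="p", sequence=seq + "A"), 1, cfg)
    assert zf.type == "C2HC" and zf.spacings == (7, 23, 1)


def test_finger_matches_enumeration_oracle(cfg, rng):
    # C/H-enriched alphabet so patterns actually occur
    letters = list("ACHG") + list("CH")
    for _ in range(250):
        n = int(rng.integers(40, 121))
        seq = "".join(rng.choice(letters, size=n))
        got = find_zinc_finger(ProteinRecord(id="r", sequence=seq), 1, cfg)
        want = finger_oracle(seq, 1, cfg.finger_search_window)
        if want is None:
            assert got is None
        else:
            assert (got.type, *got.spacings[:2], got.start) == want


def test_finger_window_limits_first_cys():
    cfg = ScanConfig(finger_search_window=3)
    seq = "AAAA" + "C" + "G" * 4 + "C" + "G" * 22 + "H" + "G" + "H" + "A"
    assert find_zinc_finger(ProteinRecord(id="p", sequence=seq), 1, cfg) is None
    assert find_zinc_finger(ProteinRecord(id="p", sequence=seq), 3, cfg) is not None


def test_invalid_spacings_rejected():
    with pytest.raises(ValueError):
        ZincFingerMotif(type="C2H2", spacings=(7, 23, 1), start=1)


# ---------------------------------------------------------------------------
# scan_protein / classification


def test_scan_complete_and_incomplete(cfg):
    finger = "C" + "A" * 4 + "C" + "A" * 22 + "H" + "A" + "H"
    p = ProteinRecord(id="p", sequence="M" * 5 + "WRKYGQK" + "A" * 10 + finger + "AA")
    hits = scan_protein(p, cfg)
    assert len(hits) == 1 and hits[0].complete
    assert hits[0].zinc_finger.start > hits[0].hepta_end
    p2 = ProteinRecord(id="q", sequence="M" * 5 + "WRKYGQK" + "A" * 40)
    hits2 = scan_protein(p2, cfg)
    assert len(hits2) == 1 and not hits2[0].complete


def _hit(ftype):
    zf = ZincFingerMotif(
        type=ftype, spacings=(4, 22, 1) if ftype == "C2H2" else (7, 23, 1), start=20
    )
    return WrkyDomainHit(heptapeptide="WRKYGQK", hepta_start=5, zinc_finger=zf, complete=True)


@pytest.mark.parametrize(
    "hits,group",
    [
        ([_hit("C2H2"), _hit("C2H2")], "1"),
        ([_hit("C2H2")], "2"),
        ([_hit("C2HC")], "3"),
        ([_hit("C2H2"), _hit("C2HC")], "ungrouped"),
        ([], "ungrouped"),
    ],
)
def test_group_assignment_rules(hits, group):
    assert classify_protein(hits).group == group


def test_classification_is_pure_function_of_hits(rng):
    cfg = ScanConfig()
    prot = make_proteome(
        {"group1": 4, "2b": 4, "group3": 4, "incomplete": 2}, seed=99
    )
    calls = {}
    for rec in prot.records:
        calls[rec.id] = classify_protein(scan_protein(rec, cfg)).group
    order = list(prot.records)
    rng.shuffle(order)
    for rec in order:
        assert classify_protein(scan_protein(rec, cfg)).group == calls[rec.id]


def test_zero_noise_proteome_labels_recovered(cfg):
    counts = {"group1": 3, "2a": 2, "2b": 2, "2c": 3, "2d": 2, "2e": 2,
              "group3": 3, "ungrouped": 2, "incomplete": 2}
    prot = make_proteome(counts, seed=17)
    for rec, (_, row) in zip(prot.records, prot.truth.iterrows()):
        hits = scan_protein(rec, cfg)
        # every planted heptapeptide recovered at its planted position
        planted = list(zip(
            row["hepta_variants"].split(";"),
            [int(x) for x in row["hepta_starts"].split(";")],
        ))
        assert [(h.heptapeptide, h.hepta_start) for h in hits] == planted
        assert classify_protein(hits).group == row["group"]
        for h, ft, fs in zip(
            [h for h in hits if h.complete],
            row["finger_types"].split(";") if row["finger_types"] else [],
            [int(x) for x in row["finger_starts"].split(";")] if row["finger_starts"] else [],
        ):
            assert (h.zinc_finger.type, h.zinc_finger.start) == (ft, fs)


# ---------------------------------------------------------------------------
# dedupe / filter


def test_dedupe_collapses_and_filters(cfg):
    finger = "C" + "A" * 4 + "C" + "A" * 22 + "H" + "A" + "H"
    full = "M" * 5 + "WRKYGQK" + "A" * 10 + finger + "AA"
    partial = "M" * 5 + "WRKYGQK" + "A" * 40
    records = [
        ProteinRecord(id="b", sequence=full),
        ProteinRecord(id="a", sequence=full),
        ProteinRecord(id="c", sequence=partial),
    ]
    hits = [scan_protein(r, cfg) for r in records]
    survivors, id_map = dedupe_and_filter(records, hits, cfg)
    assert len(survivors) == 1
    assert id_map == {"a": "WRKY1"}  # smallest id kept
    assert survivors[0].source == "a"


def test_dedupe_on_synthetic_truth(cfg):
    prot = make_proteome(
        {"group1": 3, "2b": 2, "group3": 2, "incomplete": 1, "duplicate": 2}, seed=23
    )
    hits = [scan_protein(r, cfg) for r in prot.records]
    survivors, _ = dedupe_and_filter(prot.records, hits, cfg)
    assert len(survivors) == 7  # 10 records - 2 duplicates - 1 incomplete


# ---------------------------------------------------------------------------
# protein features


def test_molecular_weight_hand_summed():
    feats = protein_features(ProteinRecord(id="p", sequence=AA))
    assert feats.molecular_weight * 1000 == pytest.approx(2395.7359, abs=1e-4)
    assert feats.orf_length == 3 * (20 + 1)


def test_pi_matches_grid_oracle():
    for seq in ("GG", "KRKRG", "DDEEG", "ACDKRHY"):
        grid_best = min(
            (abs(_net_charge(seq, p / 1000.0, DEFAULT_PKA)), p / 1000.0)
            for p in range(0, 14001)
        )[1]
        feats = protein_features(ProteinRecord(id="p", sequence=seq))
        assert feats.isoelectric_point == pytest.approx(grid_best, abs=0.01)


def test_feature_errors():
    with pytest.raises(SequenceError):
        protein_features(ProteinRecord(id="p", sequence=""))
    with pytest.raises(FeatureError):
        protein_features(ProteinRecord(id="p", sequence="MAX"))


def test_mw_monotone_and_pi_ordering(rng):
    seq = "".join(rng.choice(list(AA), size=30))
    base = protein_features(ProteinRecord(id="p", sequence=seq)).molecular_weight
    for res in AA:
        grown = protein_features(ProteinRecord(id="p", sequence=seq + res))
        assert grown.molecular_weight > base
    basic = protein_features(ProteinRecord(id="p", sequence="KKKRRRKKRG"))
    acidic = protein_features(ProteinRecord(id="p", sequence="DDDEEEDDEG"))
    assert basic.isoelectric_point > acidic.isoelectric_point
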