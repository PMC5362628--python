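"""qRT-PCR fold-change analysis and tissue-atlas breadth summaries.

Relative expression follows the 2^-ΔΔCT method: per sample,
ΔCT = mean CT(target) - mean CT(reference); across a comparison,
ΔΔCT = ΔCT(treatment) - ΔCT(control) and the expression ratio is
r = 2^-ΔΔCT.  Ratios are reported as *signed* fold changes — +r when
r >= 1 and -1/r when r < 1 — so 2-fold induction prints +2.00 and 2-fold
repression -2.00.  Regulation calls use |FC| >= 2 by default, and a
two-sided Welch t-test on replicate ΔCT values provides significance
stars (* p<0.05, ** p<0.01).

The experimental design compared has four samples crossing two genotypes
(drought-tolerant L, drought-sensitive N) with two treatments (optimal
irrigation OI, terminal drought TD): LOI, LTD, NOI, NTD.  The differential
expression table published for that experiment ships with the package as a
fixture (19 drought-responsive genes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SAMPLES",
    "COMPARISONS",
    "QpcrTable",
    "RegulationCall",
    "CallSummary",
    "ddct_fold_change",
    "classify_regulation",
    "call_gene",
    "summarize_calls",
    "atlas_summary",
    "load_table1",
    "table1_calls",
]

SAMPLES = ("LOI", "LTD", "NOI", "NTD")

#: (name, treatment, control): the two within-genotype drought contrasts
#: and the between-genotype baseline contrast.
COMPARISONS = (
    ("LOI->LTD", "LTD", "LOI"),
    ("NOI->NTD", "NTD", "NOI"),
    ("LOI->NOI", "NOI", "LOI"),
)
DROUGHT_COMPARISONS = ("LOI->LTD", "NOI->NTD")
GENOTYPE_COMPARISON = "LOI->NOI"


@dataclass
class QpcrTable:
    """CT replicates in long form: columns (sample, gene, ct)."""

    data: pd.DataFrame
    reference_gene: str = "Skip16"

    def __post_init__(self):
        need = {"sample", "gene", "ct"}
        if not need <= set(self.data.columns):
            raise ValueError(f"CT table needs columns {sorted(need)}")
        ct = self.data["ct"]
        if ((ct <= 0) | (ct >= 45)).any():
            raise ValueError("CT values must lie in (0, 45)")
        counts = self.data.groupby(["sample", "gene"]).size()
        if (counts < 3).any():
            bad = counts[counts < 3].index.tolist()[:3]
            raise ValueError(f"every (sample, gene) needs >= 3 replicates; e.g. {bad}")
        for sample in self.data["sample"].unique():
            genes = set(self.data.loc[self.data["sample"] == sample, "gene"])
            if self.reference_gene not in genes:
                raise ValueError(
                    f"reference gene {self.reference_gene!r} missing in sample {sample}"
                )

    def replicates(self, sample: str, gene: str) -> np.ndarray:
        sel = (self.data["sample"] == sample) & (self.data["gene"] == gene)
        return self.data.loc[sel, "ct"].to_numpy(dtype=float)

    def genes(self) -> list:
        return sorted(set(self.data["gene"]) - {self.reference_gene})


@dataclass(frozen=True)
class RegulationCall:
    gene_id: str
    comparison: str
    signed_fold_change: float
    direction: str  # "up" | "down" | "unchanged"
    p_value: Optional[float] = None
    significance: str = "ns"  # "ns" | "*" | "**"


@dataclass(frozen=True)
class CallSummary:
    n_responsive_genes: int
    n_up: int
    n_down: int
    n_genotype_differential: int
    n_same_pattern_both_genotypes: int
    n_down_in_LTD_and_NOI: int


# ---------------------------------------------------------------------------
# ddCT


def _delta_ct_replicates(table: QpcrTable, sample: str, gene: str) -> np.ndarray:
    g = table.replicates(sample, gene)
    r = table.replicates(sample, table.reference_gene)
    if len(g) < 2 or len(r) < 2:
        raise ValueError(f"need >= 2 replicates for {gene}/{table.reference_gene} in {sample}")
    if len(g) == len(r):
        return g - r  # replicate-paired
    return g - r.mean()


def signed_fc(ratio: float) -> float:
    """Map an expression ratio to the signed fold-change convention."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio if ratio >= 1 else -1.0 / ratio


def ddct_fold_change(
    table: QpcrTable, gene: str, treatment: str, control: str
) -> Tuple[float, float, float]:
    """Signed fold change, Welch p-value, and the raw ratio 2^-ΔΔCT."""
    dct_t = _delta_ct_replicates(table, treatment, gene)
    dct_c = _delta_ct_replicates(table, control, gene)
    ddct = dct_t.mean() - dct_c.mean()
    ratio = 2.0 ** (-ddct)
    if np.allclose(dct_t, dct_t[0]) and np.allclose(dct_c, dct_c[0]):
        p = 1.0 if np.isclose(dct_t[0], dct_c[0]) else 0.0  # degenerate zero-variance case
    else:
        p = float(stats.ttest_ind(dct_t, dct_c, equal_var=False).pvalue)
    return signed_fc(ratio), p, ratio


def classify_regulation(signed_fold_change: float, threshold: float = 2.0) -> str:
    if signed_fold_change >= threshold:
        return "up"
    if signed_fold_change <= -threshold:
        return "down"
    return "unchanged"


def _stars(p: Optional[float]) -> str:
    if p is None:
        return "ns"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def call_gene(
    table: QpcrTable, gene: str, threshold: float = 2.0,
    comparisons: Sequence[tuple] = COMPARISONS,
) -> list:
    """Regulation calls for one gene across the standard comparisons."""
    calls = []
    for name, treatment, control in comparisons:
        fc, p, _ = ddct_fold_change(table, gene, treatment, control)
        calls.append(
            RegulationCall(
                gene_id=gene,
                comparison=name,
                signed_fold_change=fc,
                direction=classify_regulation(fc, threshold),
                p_value=p,
                significance=_stars(p),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# summaries


def summarize_calls(calls: Sequence[RegulationCall]) -> CallSummary:
    """Gene-level summary of regulation calls.

    A gene is responsive if any comparison is up/down.  Each gene counts
    once, under the direction of its drought-contrast calls (LOI->LTD /
    NOI->NTD); genes with only a genotype (LOI->NOI) call count under that
    direction.  Genotype-differential genes are those with an up/down
    LOI->NOI call; same-pattern genes respond identically (and not
    "unchanged") in both genotypes' drought contrasts.
    """
    by_gene: dict = {}
    for c in calls:
        prev = by_gene.setdefault(c.gene_id, {}).get(c.comparison)
        if prev is not None:
            if prev.direction != c.direction or not math.isclose(
                prev.signed_fold_change, c.signed_fold_change
            ):
                raise ValueError(f"conflicting duplicate call for {c.gene_id}/{c.comparison}")
            continue
        by_gene[c.gene_id][c.comparison] = c
    n_resp = n_up = n_down = n_geno = n_same = n_down_both = 0
    for gene in by_gene:
        cmps = by_gene[gene]
        directions = {k: v.direction for k, v in cmps.items()}
        active = [d for d in directions.values() if d != "unchanged"]
        if not active:
            continue
        n_resp += 1
        primary = None
        for name in DROUGHT_COMPARISONS:
            if directions.get(name) not in (None, "unchanged"):
                primary = directions[name]
                break
        if primary is None:
            primary = directions.get(GENOTYPE_COMPARISON)
        if primary == "up":
            n_up += 1
        elif primary == "down":
            n_down += 1
        if directions.get(GENOTYPE_COMPARISON) in ("up", "down"):
            n_geno += 1
        d_l = directions.get("LOI->LTD")
        d_n = directions.get("NOI->NTD")
        if d_l is not None and d_l == d_n and d_l != "unchanged":
            n_same += 1
        if directions.get("LOI->LTD") == "down" and directions.get(GENOTYPE_COMPARISON) == "down":
            n_down_both += 1
    return CallSummary(
        n_responsive_genes=n_resp,
        n_up=n_up,
        n_down=n_down,
        n_genotype_differential=n_geno,
        n_same_pattern_both_genotypes=n_same,
        n_down_in_LTD_and_NOI=n_down_both,
    )


def calls_to_table(calls: Sequence[RegulationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "comparison": c.comparison,
                "signed_fold_change": round(c.signed_fold_change, 4),
                "direction": c.direction,
                "p_value": c.p_value,
                "significance": c.significance,
            }
            for c in calls
        ],
        columns=[
            "gene_id", "comparison", "signed_fold_change",
            "direction", "p_value", "significance",
        ],
    )


# ---------------------------------------------------------------------------
# tissue atlas


def atlas_summary(
    atlas: pd.DataFrame, threshold: float = 0.0
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue expressed percentages and per-gene breadth classes.

    ``atlas`` is genes x tissues with nonnegative expression values;
    "expressed" means value > threshold.  Breadth classes: ``constitutive``
    (all tissues), ``tissue-specific(<tissue>)`` (exactly one), ``silent``
    (none), else ``intermediate``.
    """
    if atlas.shape[1] < 1:
        raise ValueError("atlas needs at least one tissue")
    if len(set(atlas.columns)) != atlas.shape[1]:
        raise ValueError("tissue names must be unique")
    expressed = atlas > threshold
    tissue_pct = pd.DataFrame(
        {
            "tissue": atlas.columns,
            "pct_expressed": [
                round(100.0 * expressed[t].mean(), 1) for t in atlas.columns
            ],
        }
    )
    classes = []
    n_tissues = atlas.shape[1]
    for gene, row in expressed.iterrows():
        k = int(row.sum())
        if k == n_tissues:
            cls = "constitutive"
        elif k == 1:
            cls = f"tissue-specific({row.index[row.argmax()]})"
        elif k == 0:
            cls = "silent"
        else:
            cls = "intermediate"
        classes.append({"gene_id": gene, "n_tissues_expressed": k, "breadth_class": cls})
    return tissue_pct, pd.DataFrame(classes)


# ---------------------------------------------------------------------------
# packaged differential-expression fixture


def load_table1() -> pd.DataFrame:
    """The packaged drought qRT-PCR fold-change table (19 genes)."""
    with resources.files("wrkykit.data").joinpath("table1_fold_changes.csv").open() as fh:
        return pd.read_csv(fh)


def table1_calls(threshold: float = 2.0) -> list:
    """The fixture's non-empty fold changes as regulation calls."""
    df = load_table1()
    col_to_cmp = {
        "fc_LOI_LTD": "LOI->LTD",
        "fc_NOI_NTD": "NOI->NTD",
        "fc_LOI_NOI": "LOI->NOI",
    }
    calls = []
    for _, row in df.iterrows():
        for col, cmp_name in col_to_cmp.items():
            fc = row[col]
            if pd.isna(fc):
                continue
            calls.append(
                RegulationCall(
                    gene_id=row["gene"],
                    comparison=cmp_name,
                    signed_fold_change=float(fc),
                    direction=classify_regulation(float(fc), threshold),
                )
            )
    return calls


def plot_fold_changes(calls: Sequence[RegulationCall], path) -> None:
    """Per-gene bar plot of signed fold changes (optional matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = calls_to_table(calls)
    genes = df["gene_id"].unique()
    comparisons = [c[0] for c in COMPARISONS]
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(genes)), 4))
    width = 0.8 / len(comparisons)
    for k, cmp_name in enumerate(comparisons):
        sub = df[df["comparison"] == cmp_name].set_index("gene_id")
        vals = [sub["signed_fold_change"].get(g, 0.0) for g in genes]
        ax.bar(
            np.arange(len(genes)) + k * width, vals, width=width, label=cmp_name
        )
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xticks(np.arange(len(genes)) + 0.4)
    ax.set_xticklabels(genes, rotation=90, fontsize=7)
    ax.set_ylabel("signed fold change")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
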