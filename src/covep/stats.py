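"""Benchmark statistics over the per-variant effect table.

Compares isolated (single-variant baseline) versus neighborhood stop-gain
predictions, tallies amino-acid-changing (aa_N) against amino-acid-
preserving (aa_S) SNVs per gene, and tests whether premature-stop genes show
elevated aa_N/aa_S ratios and reduced expression (Mann-Whitney U).

The stop comparison is restricted to SNVs so frameshifts cannot contaminate
codon-level calls, and only the most upstream predicted premature stop per
gene is considered. Per-gene work uses the longest-CDS isoform as the
deterministic representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger("covep.stats")

AA_CHANGING = {"missense_variant", "stop_gained", "stop_lost", "start_lost"}
AA_PRESERVING = {"synonymous_variant", "stop_retained_variant"}

RATIO_CAP = 10.0
EXPRESSION_CLIP = 50.0


def aa_ratio(aa_n: int, aa_s: int) -> float:
    """(aa_N + 1)/(aa_S + 1) with a pseudocount in both terms, capped at 10."""
    if aa_n < 0 or aa_s < 0:
        raise ValueError("counts must be non-negative")
    return min((aa_n + 1) / (aa_s + 1), RATIO_CAP)


def _snv_effects(effects: pd.DataFrame, haplophase: str | None = None) -> pd.DataFrame:
    df = effects[effects["is_snv"]]
    if haplophase is not None:
        df = df[df["haplophase"] == haplophase]
    return df


def _representative(effects: pd.DataFrame) -> pd.DataFrame:
    """Keep rows of each gene's longest-CDS isoform (ties by transcript id)."""
    key = effects[["gene_id", "transcript_id", "cds_len"]].drop_duplicates()
    best = (
        key.sort_values(["gene_id", "cds_len", "transcript_id"],
                        ascending=[True, False, True])
        .groupby("gene_id", sort=False)
        .head(1)["transcript_id"]
    )
    return effects[effects["transcript_id"].isin(set(best))]


def first_stop_per_gene(effects: pd.DataFrame, mode: str) -> pd.Series:
    """Most-upstream stop_gained CDS position per gene for one mode.

    ``mode`` is "isolated" or "neighborhood"; SNVs only, representative
    isoform only. Genes without a stop are absent from the result.
    """
    col = {"isolated": "isolated_effect", "neighborhood": "combined_effect"}[mode]
    df = _representative(_snv_effects(effects))
    stops = df[df[col] == "stop_gained"]
    if stops.empty:
        return pd.Series(dtype=int)
    return stops.groupby("gene_id")["cds_pos"].min()


def compare_stop_modes(effects: pd.DataFrame) -> dict:
    """Contingency of stop-gain calls between the two modes.

    Variant-level (SNVs, representative isoform, deduplicated across
    phases): confirmed = stop in both modes; reclassified = isolated stop
    that the neighborhood call turns into a non-stop (typically a
    substitution); gained = neighborhood-only stop created jointly by two
    variants. Per-gene most-upstream positions for both modes are returned
    alongside.
    """
    df = _representative(_snv_effects(effects))
    df = df.drop_duplicates(subset=["variant_id", "transcript_id", "isolated_effect",
                                    "combined_effect"])
    # one premature stop codon = one (gene, transcript, codon) position, even
    # when two variants jointly create or destroy it
    key = ["gene_id", "transcript_id", "codon_index"]
    grp = df.groupby(key).agg(
        iso_stop=("isolated_effect", lambda s: (s == "stop_gained").any()),
        comb_stop=("combined_effect", lambda s: (s == "stop_gained").any()),
    )
    confirmed = int((grp["iso_stop"] & grp["comb_stop"]).sum())
    reclassified = int((grp["iso_stop"] & ~grp["comb_stop"]).sum())
    gained = int((~grp["iso_stop"] & grp["comb_stop"]).sum())
    reclass_pos = grp[grp["iso_stop"] & ~grp["comb_stop"]].index
    reclass_df = df.set_index(key).loc[reclass_pos].reset_index()
    reclass_df = reclass_df[reclass_df["isolated_effect"] == "stop_gained"]
    out = {
        "confirmed": confirmed,
        "reclassified_to_substitution": reclassified,
        "gained_in_neighborhood": gained,
        "total_isolated_stops": confirmed + reclassified,
        "reclassified_aa": reclass_df["aa_alt_combined"].value_counts().to_dict(),
        "first_stop_isolated": first_stop_per_gene(effects, "isolated"),
        "first_stop_neighborhood": first_stop_per_gene(effects, "neighborhood"),
    }
    return out


@dataclass
class GeneVariantTally:
    gene_id: str
    aa_n: int
    aa_s: int
    has_premature_stop_isolated: bool
    has_premature_stop_neighborhood: bool
    most_upstream_stop_isolated: int | None
    most_upstream_stop_neighborhood: int | None
    mean_expression: float | None = None

    @property
    def ratio(self) -> float:
        return aa_ratio(self.aa_n, self.aa_s)


def gene_tallies(effects: pd.DataFrame) -> pd.DataFrame:
    """Per-gene aa_N/aa_S counts (neighborhood-mode calls, SNVs only) and
    premature-stop flags for both modes."""
    df = _representative(_snv_effects(effects))
    df = df.drop_duplicates(subset=["variant_id", "transcript_id", "haplophase"])
    # count each physical variant once per gene even when present in 2 phases
    df = df.drop_duplicates(subset=["variant_id", "transcript_id"])
    rows = []
    iso_stops = first_stop_per_gene(effects, "isolated")
    nb_stops = first_stop_per_gene(effects, "neighborhood")
    for gene_id, sub in df.groupby("gene_id"):
        aa_n = int(sub["combined_effect"].isin(AA_CHANGING).sum())
        aa_s = int(sub["combined_effect"].isin(AA_PRESERVING).sum())
        rows.append(
            {
                "gene_id": gene_id,
                "aa_N": aa_n,
                "aa_S": aa_s,
                "ratio": aa_ratio(aa_n, aa_s),
                "has_premature_stop_isolated": gene_id in iso_stops.index,
                "has_premature_stop_neighborhood": gene_id in nb_stops.index,
                "most_upstream_stop_isolated": iso_stops.get(gene_id, np.nan),
                "most_upstream_stop_neighborhood": nb_stops.get(gene_id, np.nan),
            }
        )
    return pd.DataFrame(rows)


def group_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (normal approximation, tie-corrected).

    Returns (U statistic for the A-vs-B orientation, two-sided p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def ratio_compare(tallies: pd.DataFrame, mode: str = "neighborhood") -> dict:
    """aa_N/aa_S ratios: premature-stop genes vs all other genes with ≥1
    coding SNV. Genes with zero coding SNVs never enter ``tallies`` and are
    excluded by construction."""
    flag = f"has_premature_stop_{mode}"
    stop = tallies[tallies[flag]]["ratio"].to_numpy()
    other = tallies[~tallies[flag]]["ratio"].to_numpy()
    u, p = group_test(stop, other)
    return {
        "n_stop_genes": int(stop.size),
        "n_other_genes": int(other.size),
        "median_ratio_stop": float(np.median(stop)) if stop.size else float("nan"),
        "median_ratio_other": float(np.median(other)) if other.size else float("nan"),
        "U": u,
        "p_value": p,
        "stop_ratios": stop,
        "other_ratios": other,
    }


def expression_compare(
    count_table: pd.DataFrame, stop_gene_set: set[str], all_gene_set: set[str]
) -> dict:
    """Mean per-gene expression clipped at 50: premature-stop genes vs all
    other protein-coding genes. ``count_table`` is genes × samples with gene
    ids in the index (or first column)."""
    if not stop_gene_set:
        raise ValueError("empty premature-stop gene set")
    tbl = count_table
    if not isinstance(tbl.index, pd.Index) or tbl.index.dtype == np.int64:
        tbl = tbl.set_index(tbl.columns[0])
    means = tbl.mean(axis=1, numeric_only=True)
    missing = (stop_gene_set | all_gene_set) - set(means.index)
    if missing:
        log.warning("%d genes absent from count table; excluded", len(missing))
    stop = means.reindex(sorted(stop_gene_set & set(means.index))).clip(upper=EXPRESSION_CLIP)
    other_ids = sorted((all_gene_set - stop_gene_set) & set(means.index))
    other = means.reindex(other_ids).clip(upper=EXPRESSION_CLIP)
    u, p = group_test(stop.to_numpy(), other.to_numpy())
    return {
        "n_stop_genes": int(stop.size),
        "n_other_genes": int(other.size),
        "median_expression_stop": float(stop.median()),
        "median_expression_other": float(other.median()),
        "U": u,
        "p_value": p,
        "stop_values": stop.to_numpy(),
        "other_values": other.to_numpy(),
    }


def write_stats_outputs(tallies: pd.DataFrame, comparisons: dict, outdir) -> None:
    """Tally TSV, comparison summary TSV and violin plots."""
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tallies.to_csv(outdir / "gene_tallies.tsv", sep="\t", index=False)
    rows = []
    for name, comp in comparisons.items():
        rows.append(
            {
                "comparison": name,
                **{k: v for k, v in comp.items()
                   if isinstance(v, (int, float)) and not isinstance(v, bool)},
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "comparison_summary.tsv", sep="\t", index=False)

    panels = [
        (name, comp) for name, comp in comparisons.items()
        if "stop_ratios" in comp or "stop_values" in comp
    ]
    if panels:
        fig, axes = plt.subplots(1, len(panels), figsize=(4.5 * len(panels), 3.6),
                                 squeeze=False)
        for ax, (name, comp) in zip(axes[0], panels):
            a = comp.get("stop_ratios", comp.get("stop_values"))
            b = comp.get("other_ratios", comp.get("other_values"))
            ax.violinplot([a, b], showmedians=True)
            ax.set_xticks([1, 2], ["premature stop", "other genes"])
            ax.set_title(f"{name} (p={comp['p_value']:.2e})", fontsize=9)
        fig.tight_layout()
        fig.savefig(outdir / "violin_plots.png", dpi=120)
        plt.close(fig)
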