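"""Compensating-InDel (cInDel) detection and summary.

Within one transcript's CDS and one haplophase, InDels are walked 5'→3'
while tracking the cumulative reading-frame shift mod 3. A compensating
group starts at the first frame-disrupting InDel and closes at the first
member that returns the cumulative trace to 0; in-frame InDels occurring
while the frame is intact belong to no group, and a run that never returns
to frame is reported as an uncompensated frameshift. Groups are not limited
to pairs: any number of members may jointly restore the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .engine import TranscriptResult
from .pipeline import PipelineResult


@dataclass
class IndelRecord:
    """One InDel of a CDS, in CDS order, with its genomic anchor position."""

    variant_id: str
    cds_pos: int
    genomic_pos: int  # 0-based anchor (first trimmed ref base / insertion point)
    signed_length: int


@dataclass
class CInDelGroup:
    """An ordered set of InDels whose cumulative frame shift returns to zero."""

    transcript_id: str
    gene_id: str
    haplophase: str
    members: list[IndelRecord]
    cumulative_frame_trace: list[int]

    def __post_init__(self):
        assert self.cumulative_frame_trace[-1] == 0
        assert all(t != 0 for t in self.cumulative_frame_trace[:-1])
        assert self.net_length_change % 3 == 0

    @property
    def net_length_change(self) -> int:
        return sum(m.signed_length for m in self.members)

    @property
    def span_bp(self) -> int:
        return abs(self.members[-1].genomic_pos - self.members[0].genomic_pos)

    @property
    def pairwise_distances(self) -> list[int]:
        return [
            abs(b.genomic_pos - a.genomic_pos)
            for a, b in zip(self.members, self.members[1:])
        ]


def frame_trace(signed_lengths: list[int]) -> list[int]:
    """Cumulative frame shift (mod 3) after each InDel, in CDS order."""
    trace, total = [], 0
    for s in signed_lengths:
        total += s
        trace.append(total % 3)
    return trace


def find_cindel_groups(
    indels: list[IndelRecord],
    transcript_id: str = "",
    gene_id: str = "",
    haplophase: str = "both",
) -> tuple[list[CInDelGroup], list[IndelRecord], list[IndelRecord]]:
    """First-return grouping over CDS-ordered InDels.

    Returns (groups, inframe_singletons, uncompensated_tail): in-frame
    InDels encountered while the trace is 0 join no group; a trailing run
    that never returns to frame yields no group and is reported as an
    uncompensated frameshift.
    """
    groups: list[CInDelGroup] = []
    inframe: list[IndelRecord] = []
    open_run: list[IndelRecord] = []
    open_trace: list[int] = []
    total = 0
    for rec in sorted(indels, key=lambda r: r.cds_pos):
        if not open_run and rec.signed_length % 3 == 0:
            inframe.append(rec)
            continue
        total = (total + rec.signed_length) % 3
        open_run.append(rec)
        open_trace.append(total)
        if total == 0:
            groups.append(
                CInDelGroup(transcript_id, gene_id, haplophase, open_run, open_trace)
            )
            open_run, open_trace = [], []
    return groups, inframe, open_run


def cindels_from_pipeline(result: PipelineResult):
    """Group InDels of every analyzed transcript/haplophase.

    Phase-0/phase-1 results that contain the identical InDel set (the fully
    homozygous case) are collapsed to a single "both" entry so each physical
    group is counted once.
    """
    all_groups: list[CInDelGroup] = []
    uncompensated: list[tuple[str, str, list[IndelRecord]]] = []
    per_tx_counts: dict[str, int] = {}
    seen: set[tuple] = set()
    for tr in result.transcript_results:
        indels = [
            IndelRecord(
                cv.variant_id, cv.cds_pos, cv.variant.pos, cv.signed_length
            )
            for cv in tr.applied.variants
            if cv.signed_length != 0
        ]
        if not indels:
            continue
        key = (tr.transcript.transcript_id,
               tuple((r.variant_id, r.signed_length) for r in sorted(indels, key=lambda r: r.cds_pos)))
        if key in seen:
            continue  # identical indel set already processed for the other phase
        seen.add(key)
        per_tx_counts[tr.transcript.transcript_id] = len(indels)
        groups, _inframe, tail = find_cindel_groups(
            indels, tr.transcript.transcript_id, tr.transcript.gene_id, tr.haplophase
        )
        all_groups.extend(groups)
        if tail:
            uncompensated.append(
                (tr.transcript.transcript_id, tr.haplophase, tail)
            )
    return all_groups, uncompensated, per_tx_counts


def cindel_report(result: PipelineResult, outdir=None):
    """Summary tables: groups, per-transcript InDel counts, distance histogram.

    Distances are genomic anchor-to-anchor between consecutive group members
    (the InDel's own length is not added). Returns the three DataFrames and
    optionally writes TSVs plus a distance bar plot under ``outdir``.
    """
    groups, uncompensated, per_tx = cindels_from_pipeline(result)

    group_rows = []
    for g in groups:
        group_rows.append(
            {
                "transcript_id": g.transcript_id,
                "gene_id": g.gene_id,
                "haplophase": g.haplophase,
                "n_members": len(g.members),
                "member_ids": ";".join(m.variant_id for m in g.members),
                "signed_lengths": ";".join(str(m.signed_length) for m in g.members),
                "net_length_change_nt": g.net_length_change,
                "net_residue_change": g.net_length_change // 3,
                "span_bp": g.span_bp,
                "pairwise_distances_bp": ";".join(map(str, g.pairwise_distances)),
            }
        )
    groups_df = pd.DataFrame(
        group_rows,
        columns=["transcript_id", "gene_id", "haplophase", "n_members", "member_ids",
                 "signed_lengths", "net_length_change_nt", "net_residue_change",
                 "span_bp", "pairwise_distances_bp"],
    )

    counts_df = pd.DataFrame(
        sorted(per_tx.items()), columns=["transcript_id", "n_indels"]
    )

    distances = [d for g in groups for d in g.pairwise_distances]
    if distances:
        hist = pd.Series(distances).value_counts().sort_index()
        hist_df = pd.DataFrame({"distance_bp": hist.index, "count": hist.values})
    else:
        hist_df = pd.DataFrame(columns=["distance_bp", "count"])

    n_genes_with_group = len({g.gene_id for g in groups})
    summary = {
        "n_groups": len(groups),
        "n_genes_with_cindel": n_genes_with_group,
        "n_uncompensated_frameshift_transcripts": len(uncompensated),
        "n_transcripts_with_indels": len(per_tx),
    }

    if outdir is not None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        # document the distance convention in the output itself
        with open(outdir / "cindel_groups.tsv", "w") as fh:
            fh.write("# distances are genomic anchor-to-anchor between consecutive "
                     "members; the InDel's own length is not included\n")
            groups_df.to_csv(fh, sep="\t", index=False)
        counts_df.to_csv(outdir / "per_transcript_indel_counts.tsv", sep="\t", index=False)
        hist_df.to_csv(outdir / "distance_histogram.tsv", sep="\t", index=False)
        _plot_distances(hist_df, counts_df, outdir)

    return groups_df, counts_df, hist_df, summary


def _plot_distances(hist_df, counts_df, outdir):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    if len(hist_df):
        axes[0].bar(hist_df["distance_bp"], hist_df["count"], color="#336699")
    axes[0].set_xlabel("distance between consecutive cInDel members (bp)")
    axes[0].set_ylabel("count")
    if len(counts_df):
        vc = counts_df["n_indels"].value_counts().sort_index()
        axes[1].bar(vc.index, vc.values, color="#993333")
    axes[1].set_xlabel("InDels per transcript")
    axes[1].set_ylabel("transcripts")
    fig.tight_layout()
    fig.savefig(outdir / "cindel_plots.png", dpi=120)
    plt.close(fig)
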