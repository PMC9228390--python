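"""Multi-assembler merge: pooled clustering, common/unique buckets, accounting.

Different de novo assemblers recover overlapping but non-identical gene
sets; pooling their per-assembler non-redundant ORF sets and clustering
the pool at the same identity threshold labels each cluster by its source
span. Clusters spanning every assembler are "common", those confined to
one are "unique" to it, and clusters spanning exactly two sit in between.
Published accountings often fold the two-assembler clusters into the
common bucket so that common + uniques equals the merged total; the
``paper_mode`` flag reproduces that convention while the strict buckets
remain available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .cluster import Cluster, ClusterConfig, ClusterSet, cluster_self
from .seqio import SequenceRecord

__all__ = [
    "MergeBuckets",
    "MergeReport",
    "merge_assemblies",
    "merged_total",
    "merge_report",
    "percent_change",
    "merge_report_tsv",
]


@dataclass
class MergeBuckets:
    """Clusters bucketed by the set of assemblers their members came from."""

    common: list[Cluster] = field(default_factory=list)
    shared_pair: list[Cluster] = field(default_factory=list)
    unique_per_source: dict[str, list[Cluster]] = field(default_factory=dict)
    paper_mode: bool = False

    def counts(self) -> dict[str, int]:
        """Bucket sizes; in paper mode shared-pair counts fold into common."""
        out: dict[str, int] = {}
        if self.paper_mode:
            out["common"] = len(self.common) + len(self.shared_pair)
        else:
            out["common"] = len(self.common)
            out["shared_pair"] = len(self.shared_pair)
        for src in sorted(self.unique_per_source):
            out[f"unique:{src}"] = len(self.unique_per_source[src])
        return out

    @property
    def total(self) -> int:
        return (
            len(self.common)
            + len(self.shared_pair)
            + sum(len(v) for v in self.unique_per_source.values())
        )


@dataclass
class MergeReport:
    """Per-bucket annotation accounting (totals, annotated, percentages)."""

    total_sequences: int
    per_bucket_totals: dict[str, int]
    annotated: dict[str, int]
    without_annotation: dict[str, int]
    contribution_to_unannotated: dict[str, float | None]
    distribution_of_annotated: dict[str, float | None]

    @property
    def total_annotated(self) -> int:
        return sum(self.annotated.values())

    @property
    def total_unannotated(self) -> int:
        return sum(self.without_annotation.values())


def merge_assemblies(
    orf_sets: Mapping[str, Sequence[SequenceRecord]],
    config: ClusterConfig | None = None,
    *,
    paper_mode: bool = False,
) -> tuple[ClusterSet, MergeBuckets, list[SequenceRecord]]:
    """Pool per-assembler ORF sets, cluster, and bucket by source span.

    Each input set should already be internally non-redundant (apply
    :func:`~toxprospect.cluster.cluster_self` per assembler first). The
    pooled records are clustered at the configured threshold; each
    cluster is labeled common / shared-pair / unique according to how
    many source sets its members span, and the merged non-redundant set
    is the list of longest representatives, one per cluster.
    """
    if len(orf_sets) < 2:
        raise ValueError("merge_assemblies requires at least two source sets")
    config = config or ClusterConfig()
    pooled: list[SequenceRecord] = []
    seen_ids: set[str] = set()
    for src, records in orf_sets.items():
        for rec in records:
            if rec.id in seen_ids:
                raise ValueError(f"record id {rec.id!r} occurs in more than one source set")
            seen_ids.add(rec.id)
            pooled.append(SequenceRecord(rec.id, rec.seq, source=src))
    cs = cluster_self(pooled, config)
    n_sources = len(orf_sets)
    buckets = MergeBuckets(paper_mode=paper_mode)
    for src in orf_sets:
        buckets.unique_per_source[src] = []
    for cl in cs.clusters:
        span = cl.sources
        if len(span) >= n_sources:
            buckets.common.append(cl)
        elif len(span) == 2:
            buckets.shared_pair.append(cl)
        else:
            buckets.unique_per_source[next(iter(span))].append(cl)
    merged = [cl.representative for cl in cs.clusters]
    return cs, buckets, merged


def merged_total(bucket_counts: Sequence[int]) -> int:
    """Total of the merged set from its bucket counts (common + uniques)."""
    counts = list(bucket_counts)
    if any(c < 0 for c in counts):
        raise ValueError("bucket counts must be non-negative")
    return sum(counts)


def merge_report(
    bucket_counts: Mapping[str, int], annotated_counts: Mapping[str, int]
) -> MergeReport:
    """Build the annotation-contribution accounting for merged buckets.

    Per bucket: without_annotation = total - annotated; contribution % =
    bucket_unannotated / total_unannotated * 100; distribution % =
    bucket_annotated / total_annotated * 100, each to two decimals.
    Degenerate denominators (no unannotated, or no annotated, sequences
    anywhere) yield ``None`` ("NA") percentages.
    """
    if set(annotated_counts) != set(bucket_counts):
        raise ValueError("bucket_counts and annotated_counts must share keys")
    without: dict[str, int] = {}
    for k, total in bucket_counts.items():
        ann = annotated_counts[k]
        if ann > total:
            raise ValueError(f"bucket {k!r}: annotated ({ann}) exceeds total ({total})")
        if ann < 0 or total < 0:
            raise ValueError(f"bucket {k!r}: negative count")
        without[k] = total - ann
    total_ann = sum(annotated_counts.values())
    total_un = sum(without.values())
    contribution = {
        k: (round(100.0 * v / total_un, 2) if total_un else None) for k, v in without.items()
    }
    distribution = {
        k: (round(100.0 * annotated_counts[k] / total_ann, 2) if total_ann else None)
        for k in bucket_counts
    }
    return MergeReport(
        total_sequences=sum(bucket_counts.values()),
        per_bucket_totals=dict(bucket_counts),
        annotated=dict(annotated_counts),
        without_annotation=without,
        contribution_to_unannotated=contribution,
        distribution_of_annotated=distribution,
    )


def percent_change(new: int | float, old: int | float) -> int:
    """Percent change from ``old`` to ``new``, rounded to the nearest integer."""
    if old <= 0:
        raise ValueError("old count must be positive")
    return round(100.0 * (new - old) / old)


def merge_report_tsv(report: MergeReport) -> str:
    """Render the merge accounting as a TSV table (buckets as columns)."""
    def pct(v: float | None) -> str:
        return "NA" if v is None else f"{v:.2f}%"

    keys = list(report.per_bucket_totals)
    lines = ["\tMerged File\t" + "\t".join(keys)]
    lines.append(
        "Total sequences\t{}\t".format(report.total_sequences)
        + "\t".join(str(report.per_bucket_totals[k]) for k in keys)
    )
    lines.append(
        "Annotated\t{}\t".format(report.total_annotated)
        + "\t".join(str(report.annotated[k]) for k in keys)
    )
    lines.append(
        "Without annotation\t{}\t".format(report.total_unannotated)
        + "\t".join(str(report.without_annotation[k]) for k in keys)
    )
    lines.append(
        "Contribution to sequences without annotation\tNA\t"
        + "\t".join(pct(report.contribution_to_unannotated[k]) for k in keys)
    )
    lines.append(
        "Distribution of annotated sequences\tNA\t"
        + "\t".join(pct(report.distribution_of_annotated[k]) for k in keys)
    )
    return "\n".join(lines) + "\n"
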