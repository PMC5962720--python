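"""Sequencing-error correction by singleton collapsing.

PCR and sequencing errors typically create spurious clonotypes observed
exactly once (singletons) that sit one edit away from a genuinely abundant
clonotype. Within each TRBV-TRBJ cluster, a singleton is folded into a
non-singleton clonotype when their CDR3 peptides are at Levenshtein
distance 1 AND the corresponding CDR3 nucleotide sequences are also at
distance 1 (for at least one nucleotide variant of the target). Total
sequence count is always conserved.

When several non-singleton targets are eligible, the most abundant one is
chosen (the maximum-likelihood source of a single-base error), ties broken
by lexicographic CDR3 peptide. Merging is a single pass against the
original non-singleton set: results do not depend on processing order and
no cascading re-evaluation occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import pandas as pd

from .repio import ClonotypeTable, SequenceRecord

__all__ = [
    "levenshtein",
    "VJCluster",
    "NonSingleton",
    "build_clusters",
    "collapse_singletons",
    "correct_dataset",
]


def levenshtein(a: str, b: str) -> int:
    """Levenshtein edit distance between two strings.

    Minimum number of single-character insertions, deletions or
    substitutions turning *a* into *b*.
    """
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def _edit_position(a: str, b: str) -> int:
    """0-based position of the single edit between distance-1 strings."""
    for i, (ca, cb) in enumerate(zip(a, b)):
        if ca != cb:
            return i
    return min(len(a), len(b))  # trailing insertion/deletion


@dataclass
class NonSingleton:
    """A clonotype observed at least twice, with its nucleotide variants."""

    cdr3_aa: str
    nt_variants: set[str]
    count: int


@dataclass
class VJCluster:
    """All clonotypes sharing one TRBV-TRBJ combination."""

    v_gene: str
    j_gene: str
    singletons: list[SequenceRecord] = field(default_factory=list)
    nonsingletons: list[NonSingleton] = field(default_factory=list)


def build_clusters(records: Iterable[SequenceRecord]) -> list[VJCluster]:
    """Group records into TRBV-TRBJ clusters, splitting singletons.

    A clonotype is a singleton iff its total count across records is 1;
    non-singletons carry the set of distinct nucleotide variants observed.
    """
    by_clone: dict[tuple[str, str, str], dict] = {}
    for rec in records:
        k = (rec.v_gene, rec.cdr3_aa, rec.j_gene)
        slot = by_clone.setdefault(k, {"count": 0, "nts": set(), "rec": rec})
        slot["count"] += int(rec.count)
        slot["nts"].add(rec.cdr3_nt)
    clusters: dict[tuple[str, str], VJCluster] = {}
    for (v, aa, j), slot in by_clone.items():
        cluster = clusters.setdefault((v, j), VJCluster(v, j))
        if slot["count"] == 1:
            cluster.singletons.append(slot["rec"])
        else:
            cluster.nonsingletons.append(
                NonSingleton(cdr3_aa=aa, nt_variants=slot["nts"], count=slot["count"])
            )
    return list(clusters.values())


def collapse_singletons(cluster: VJCluster) -> tuple[VJCluster, pd.DataFrame]:
    """Merge erroneous singletons of one cluster into their 1-edit targets.

    Returns the corrected cluster and a merge log with one row per merged
    singleton (cluster V/J, singleton CDR3 aa/nt, target CDR3 aa, and the
    0-based amino-acid edit position).
    """
    merges: list[dict] = []
    kept_singletons: list[SequenceRecord] = []
    # Deep-ish copy so the input cluster is not mutated.
    new_ns = [
        NonSingleton(ns.cdr3_aa, set(ns.nt_variants), ns.count)
        for ns in cluster.nonsingletons
    ]
    # Eligibility and tie-breaking use the ORIGINAL counts (single pass).
    original = cluster.nonsingletons
    for single in cluster.singletons:
        candidates = []
        for idx, ns in enumerate(original):
            if levenshtein(single.cdr3_aa, ns.cdr3_aa) != 1:
                continue
            if any(levenshtein(single.cdr3_nt, nt) == 1 for nt in ns.nt_variants):
                candidates.append(idx)
        if candidates:
            best = min(candidates, key=lambda i: (-original[i].count, original[i].cdr3_aa))
            new_ns[best].count += single.count
            merges.append(
                {
                    "cluster_v": cluster.v_gene,
                    "cluster_j": cluster.j_gene,
                    "singleton_aa": single.cdr3_aa,
                    "singleton_nt": single.cdr3_nt,
                    "target_aa": original[best].cdr3_aa,
                    "aa_edit_position": _edit_position(
                        single.cdr3_aa, original[best].cdr3_aa
                    ),
                }
            )
        else:
            kept_singletons.append(single)
    corrected = VJCluster(
        cluster.v_gene, cluster.j_gene, kept_singletons, new_ns
    )
    return corrected, pd.DataFrame(
        merges,
        columns=[
            "cluster_v", "cluster_j", "singleton_aa", "singleton_nt",
            "target_aa", "aa_edit_position",
        ],
    )


def correct_dataset(
    records: Sequence[SequenceRecord], sample_id: str = ""
) -> tuple[ClonotypeTable, pd.DataFrame]:
    """Error-correct a dataset of annotated sequences.

    Clusters records per TRBV-TRBJ combination, collapses erroneous
    singletons (single pass, no fixpoint iteration) and aggregates the
    result into a clonotype table. Total sequence count is conserved.
    """
    clusters = build_clusters(records)
    entries: dict = {}
    logs = []
    for cluster in clusters:
        corrected, log = collapse_singletons(cluster)
        logs.append(log)
        for single in corrected.singletons:
            key = single.key
            entries[key] = entries.get(key, 0) + int(single.count)
        for ns in corrected.nonsingletons:
            key = (cluster.v_gene, ns.cdr3_aa, cluster.j_gene)
            entries[key] = entries.get(key, 0) + int(ns.count)
    report = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(
            columns=[
                "cluster_v", "cluster_j", "singleton_aa", "singleton_nt",
                "target_aa", "aa_edit_position",
            ]
        )
    )
    table = ClonotypeTable(entries, sample_id=sample_id)
    return table, report
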