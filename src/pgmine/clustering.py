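"""Greedy incremental identity clustering of peptide sequences.

Redundant transcripts for the same enzyme function are collapsed the way
CD-HIT does it: sequences are visited from longest to shortest and each
one either joins the first existing cluster whose representative it
matches at or above the identity threshold, or founds a new cluster as
representative ("head").  Two choices that CD-HIT leaves configurable
are pinned down here so results are reproducible:

* identity between two peptides is the number of identical residues in
  an optimal global alignment (match 1, mismatch 0, zero gap penalty —
  i.e. the longest-common-subsequence length) divided by the length of
  the SHORTER sequence;
* visiting order is length-descending with ties broken by ascending
  sequence id.

A residue-multiset upper bound on the alignment score is used to skip
pairs that cannot possibly reach the threshold; the bound is exact, so
the prefilter can never change the clustering relative to the
brute-force oracle :func:`brute_force_cluster`.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import Align

from .mining import FunctionAssignment

_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=0.0,
    open_gap_score=0.0,
    extend_gap_score=0.0,
)


@dataclasses.dataclass
class SequenceCluster:
    """One greedy-identity cluster: a representative head plus members."""

    cluster_id: int
    representative_id: str
    member_ids: list[str]
    identity_threshold: float
    function_code: str | None = None
    species: str | None = None


@dataclasses.dataclass
class PurityReport:
    """Whether pooled clusters mix species or functions."""

    n_clusters: int
    n_pure: int
    impure_cluster_ids: list[int]

    @property
    def fraction_pure(self) -> float | None:
        """Fraction of pure clusters; ``None`` when there are no clusters."""
        if self.n_clusters == 0:
            return None
        return self.n_pure / self.n_clusters


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues, relative to the shorter sequence.

    Symmetric, in [0, 1]; a perfect prefix/suffix pair scores 1.0.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return _ALIGNER.score(a, b) / min(len(a), len(b))


def _identity_upper_bound(a: str, b: str) -> float:
    # LCS length can never exceed the shared residue multiset size.
    shared = sum((Counter(a) & Counter(b)).values())
    return shared / min(len(a), len(b))


def _greedy(
    sequences: Mapping[str, str],
    threshold: float,
    *,
    prefilter: bool,
    function_code: str | None,
    species: str | None,
) -> list[SequenceCluster]:
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not sequences:
        raise ValueError("at least one sequence is required")
    for sid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence for id {sid!r}")
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    clusters: list[SequenceCluster] = []
    for sid in order:
        seq = sequences[sid]
        placed = False
        for cluster in clusters:
            rep = sequences[cluster.representative_id]
            if prefilter and _identity_upper_bound(seq, rep) < threshold:
                continue
            if pairwise_identity(seq, rep) >= threshold:
                cluster.member_ids.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(
                SequenceCluster(
                    cluster_id=len(clusters),
                    representative_id=sid,
                    member_ids=[sid],
                    identity_threshold=threshold,
                    function_code=function_code,
                    species=species,
                )
            )
    return clusters


def greedy_cluster(
    sequences: Mapping[str, str],
    threshold: float = 0.9,
    *,
    function_code: str | None = None,
    species: str | None = None,
) -> list[SequenceCluster]:
    """Cluster sequences greedily at the given amino-acid identity threshold."""
    return _greedy(
        sequences,
        threshold,
        prefilter=True,
        function_code=function_code,
        species=species,
    )


def brute_force_cluster(
    sequences: Mapping[str, str], threshold: float = 0.9
) -> list[SequenceCluster]:
    """Test oracle: the same greedy contract with no prefilter, <= 50 sequences."""
    if len(sequences) > 50:
        raise ValueError("brute_force_cluster is limited to <= 50 sequences")
    return _greedy(
        sequences, threshold, prefilter=False, function_code=None, species=None
    )


def cluster_by_function(
    assignments: list[FunctionAssignment],
    peptides: Mapping[str, str],
    threshold: float = 0.9,
) -> tuple[list[SequenceCluster], pd.DataFrame]:
    """Cluster independently within each (species, function) group.

    Returns the clusters plus a report with one row per group:
    ``sp_count`` (transcripts before clustering, i.e. annotation-table
    hits) and ``cdhit_count`` (clusters after collapsing redundancy).
    """
    groups: dict[tuple[str, str], set[str]] = {}
    for a in assignments:
        groups.setdefault((a.species, a.function_code), set()).add(a.transcript_id)
    missing = sorted(
        {tid for ids in groups.values() for tid in ids if not peptides.get(tid)}
    )
    if missing:
        raise ValueError(f"missing peptide sequences for: {missing}")

    clusters: list[SequenceCluster] = []
    rows = []
    next_id = 0
    for (species, code), ids in sorted(groups.items()):
        sub = {tid: peptides[tid] for tid in ids}
        group_clusters = greedy_cluster(
            sub, threshold, function_code=code, species=species
        )
        for c in group_clusters:
            c.cluster_id = next_id
            next_id += 1
            clusters.append(c)
        rows.append(
            {
                "species": species,
                "function_code": code,
                "sp_count": len(ids),
                "cdhit_count": len(group_clusters),
            }
        )
    report = pd.DataFrame(
        rows, columns=["species", "function_code", "sp_count", "cdhit_count"]
    )
    return clusters, report


def cross_species_purity(
    clusters: list[SequenceCluster],
    species_of: Mapping[str, str],
    functions_of: Mapping[str, set[str]],
) -> PurityReport:
    """Check clusters from a pooled all-species run for mixing.

    A cluster is pure when its members come from a single species and
    share at least one common function.
    """
    impure = []
    for c in clusters:
        species = {species_of[m] for m in c.member_ids}
        common = set.intersection(*(set(functions_of[m]) for m in c.member_ids))
        if len(species) != 1 or not common:
            impure.append(c.cluster_id)
    return PurityReport(
        n_clusters=len(clusters),
        n_pure=len(clusters) - len(impure),
        impure_cluster_ids=impure,
    )


def write_clstr(
    clusters: list[SequenceCluster],
    peptides: Mapping[str, str],
    path: str | Path,
) -> Path:
    """Write clusters in CD-HIT's ``.clstr`` text format."""
    path = Path(path)
    lines = []
    for c in clusters:
        lines.append(f">Cluster {c.cluster_id}")
        rep = peptides[c.representative_id]
        for i, mid in enumerate(c.member_ids):
            seq = peptides[mid]
            if mid == c.representative_id:
                lines.append(f"{i}\t{len(seq)}aa, >{mid}... *")
            else:
                pct = 100.0 * pairwise_identity(seq, rep)
                lines.append(f"{i}\t{len(seq)}aa, >{mid}... at {pct:.2f}%")
    path.write_text("\n".join(lines) + "\n")
    return path
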