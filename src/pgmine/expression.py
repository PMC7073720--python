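"""FPKM quantification and per-function aggregation.

Per-transcript expression is quantified as fragments per kilobase of
transcript per million mapped read pairs:

    FPKM = mapped_read_pairs / (length_bp / 1000) / (total_read_pairs / 1e6)

When a function is represented by several transcripts in a
transcriptome, the expression of the function is the SUM of the
contributing FPKM values.  The contributing set defaults to cluster
heads — one transcript per gene after redundancy collapsing — and can be
switched to all assigned transcripts.  Because clustering pools a
species' replicate transcriptomes, the "head" used inside one
transcriptome is that transcriptome's longest member of each cluster
(ties broken by ascending id); this local-head rule guarantees every
transcriptome in which a function is annotated gets an expression
record.

Absence is meaningful: a function with no assigned transcript in a
transcriptome yields no record at all, which downstream matrices encode
as a missing cell, never as zero.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal, Mapping

import math

import pandas as pd

from .clustering import SequenceCluster
from .io import TranscriptomeBundle
from .mining import FunctionAssignment

SumMode = Literal["heads", "all"]


@dataclasses.dataclass(frozen=True)
class FunctionExpression:
    """Summed FPKM for one function in one transcriptome."""

    mmetsp_code: str
    function_code: str
    fpkm_sum: float
    n_transcripts: int


def compute_fpkm(
    mapped_read_pairs: int, transcript_length: int, total_read_pairs: int
) -> float:
    """Evaluate the FPKM formula for one transcript."""
    if transcript_length < 1:
        raise ValueError("transcript_length must be >= 1")
    if total_read_pairs < 1:
        raise ValueError("total_read_pairs must be >= 1")
    if mapped_read_pairs < 0:
        raise ValueError("mapped_read_pairs must be >= 0")
    return mapped_read_pairs / (transcript_length / 1000.0) / (total_read_pairs / 1e6)


def bundle_fpkm(bundle: TranscriptomeBundle) -> dict[str, float]:
    """Per-transcript FPKM for every transcript in a bundle."""
    return {
        t.transcript_id: compute_fpkm(
            t.mapped_read_pairs, t.nucleotide_length, bundle.total_read_pairs
        )
        for t in bundle.transcripts
    }


def function_expression(
    assignments: Iterable[FunctionAssignment],
    clusters: list[SequenceCluster],
    expression: Mapping[str, float],
    lengths: Mapping[str, int] | None = None,
    mode: SumMode = "heads",
) -> list[FunctionExpression]:
    """Aggregate per-transcript FPKM into per-(transcriptome, function) sums.

    ``expression`` maps transcript id to FPKM; ``lengths`` (required in
    ``"heads"`` mode) maps transcript id to nucleotide length for the
    local-head choice.  An assignment with no expression record is
    fatal.
    """
    assignments = list(assignments)
    missing = sorted({a.transcript_id for a in assignments} - set(expression))
    if missing:
        raise ValueError(f"assignments without expression records: {missing}")

    transcriptome_of = {a.transcript_id: a.mmetsp_code for a in assignments}
    assigned: dict[tuple[str, str], set[str]] = {}
    for a in assignments:
        assigned.setdefault((a.mmetsp_code, a.function_code), set()).add(
            a.transcript_id
        )

    contributing: dict[tuple[str, str], set[str]] = {}
    if mode == "all":
        contributing = assigned
    elif mode == "heads":
        if lengths is None:
            raise ValueError("heads mode requires transcript lengths")
        for cluster in clusters:
            per_code: dict[str, list[str]] = {}
            for mid in cluster.member_ids:
                code = transcriptome_of.get(mid)
                if code is not None:
                    per_code.setdefault(code, []).append(mid)
            for code, members in per_code.items():
                head = min(members, key=lambda m: (-lengths[m], m))
                key = (code, cluster.function_code or "")
                contributing.setdefault(key, set()).add(head)
    else:
        raise ValueError(f"unknown sum mode {mode!r}")

    out = [
        FunctionExpression(
            mmetsp_code=code,
            function_code=fcode,
            fpkm_sum=math.fsum(expression[tid] for tid in ids),
            n_transcripts=len(ids),
        )
        for (code, fcode), ids in sorted(contributing.items())
        if ids
    ]
    return out


def expression_matrix(
    function_expressions: Iterable[FunctionExpression],
    grouping: Literal["transcriptome", "species"] = "transcriptome",
    species_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Functions x transcriptomes FPKM table with missing cells as NaN.

    With ``grouping="species"`` the columns are relabelled
    ``"species|mmetsp_code"`` and ordered so each species' replicate
    transcriptomes form a contiguous block.
    """
    records = list(function_expressions)
    if not records:
        return pd.DataFrame()
    df = pd.DataFrame(
        [(r.function_code, r.mmetsp_code, r.fpkm_sum) for r in records],
        columns=["function_code", "mmetsp_code", "fpkm_sum"],
    )
    matrix = df.pivot_table(
        index="function_code", columns="mmetsp_code", values="fpkm_sum"
    )
    from .vocabulary import FUNCTION_ORDER

    row_order = [c for c in FUNCTION_ORDER if c in matrix.index] + sorted(
        set(matrix.index) - set(FUNCTION_ORDER)
    )
    matrix = matrix.loc[row_order]
    if grouping == "species":
        if species_of is None:
            raise ValueError("species grouping requires a mmetsp->species mapping")
        cols = sorted(matrix.columns, key=lambda c: (species_of.get(c, ""), c))
        matrix = matrix[cols]
        matrix.columns = [f"{species_of.get(c, '')}|{c}" for c in cols]
    else:
        matrix = matrix[sorted(matrix.columns)]
    matrix.index.name = "function_code"
    return matrix
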