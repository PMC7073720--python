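"""Keyword mining of annotation tables against the enzyme vocabulary.

The mining stage is deliberately simple, mirroring how annotation-table
surveys are actually done: a case-insensitive substring query (default
term ``"prostaglandin"``) pulls candidate hits out of each
transcriptome's Swiss-Prot table, and each hit description is then
canonicalized against the nine-function vocabulary by
longest-synonym-first substring matching.  Term-matching descriptions
that canonicalize to no vocabulary entry (e.g. "Prostaglandin
transporter") are reported as unmapped rather than silently dropped, so
the vocabulary stays auditable.
"""

from __future__ import annotations

import dataclasses

from .io import AnnotationHit, TranscriptomeBundle
from .vocabulary import EnzymeFunction


@dataclasses.dataclass(frozen=True)
class FunctionAssignment:
    """One transcript assigned to one vocabulary function."""

    transcript_id: str
    mmetsp_code: str
    species: str
    function_code: str
    matched_description: str


@dataclasses.dataclass
class MiningResult:
    """Assignments plus the audit trail of unmapped term-matching hits."""

    assignments: list[FunctionAssignment]
    unmapped: list[AnnotationHit]

    @property
    def n_unmapped(self) -> int:
        return len(self.unmapped)


def query_annotations(bundle: TranscriptomeBundle, term: str) -> list[AnnotationHit]:
    """Hits whose description contains ``term``, case-insensitively.

    Input order is preserved.
    """
    if not term:
        raise ValueError("query term must be non-empty")
    needle = term.lower()
    return [h for h in bundle.annotations if needle in h.description.lower()]


def canonicalize(
    description: str, vocabulary: list[EnzymeFunction]
) -> str | None:
    """Map a free-text hit description to a function code, or ``None``.

    Synonyms are tried longest-first so that e.g. a full Swiss-Prot
    protein name wins over a short abbreviation embedded in it; matching
    is case-insensitive substring containment.
    """
    if not description:
        raise ValueError("description must be non-empty")
    haystack = description.lower()
    pairs = [(syn, e.code) for e in vocabulary for syn in e.synonyms]
    pairs.sort(key=lambda p: (-len(p[0]), p[0]))
    for syn, code in pairs:
        if syn.lower() in haystack:
            return code
    return None


def assign_functions(
    bundle: TranscriptomeBundle,
    vocabulary: list[EnzymeFunction],
    term: str = "prostaglandin",
) -> MiningResult:
    """Compose the term query and canonicalization for one bundle.

    Duplicate (transcript, function) pairs collapse to one assignment;
    the retained ``matched_description`` is the lexicographically
    smallest matching description so the result is invariant under
    annotation-row order.  A transcript whose hits name two different
    functions keeps both assignments.
    """
    matched: dict[tuple[str, str], str] = {}
    unmapped: list[AnnotationHit] = []
    for hit in query_annotations(bundle, term):
        code = canonicalize(hit.description, vocabulary)
        if code is None:
            unmapped.append(hit)
            continue
        key = (hit.transcript_id, code)
        if key not in matched or hit.description < matched[key]:
            matched[key] = hit.description
    assignments = [
        FunctionAssignment(
            transcript_id=tid,
            mmetsp_code=bundle.mmetsp_code,
            species=bundle.species,
            function_code=code,
            matched_description=desc,
        )
        for (tid, code), desc in sorted(matched.items())
    ]
    unmapped.sort(key=lambda h: (h.transcript_id, h.description, h.start))
    return MiningResult(assignments=assignments, unmapped=unmapped)
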