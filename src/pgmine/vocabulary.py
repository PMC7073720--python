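"""The nine-enzyme prostaglandin-metabolism vocabulary.

Transcriptome mining for the prostaglandin (Pg) pathway rests on a
controlled vocabulary of the nine enzyme functions recoverable from
Swiss-Prot annotation of dinoflagellate transcriptomes: six involved in
Pg synthesis (the pathway-initiating cyclooxygenase COX2, the terminal
synthases HPGDS, PTGES2, PTGFS1, PTGFS2 and the PGE2 9-oxo-reductase)
and three in Pg catabolism/inactivation (15-PGDH, PTGR1, PTGR2).  Each
entry carries the synonym strings under which Swiss-Prot hits for that
function appear, so that free-text hit descriptions can be canonicalized
to a stable function code.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

SYNTHESIS = "synthesis"
CATABOLISM = "catabolism"

#: Fixed column/reporting order for the nine function codes.
FUNCTION_ORDER = [
    "COX2",
    "HPGDS",
    "PTGES2",
    "PGE2-9-OR",
    "15-PGDH",
    "PTGFS1",
    "PTGFS2",
    "PTGR1",
    "PTGR2",
]


@dataclasses.dataclass(frozen=True)
class EnzymeFunction:
    """One controlled-vocabulary entry for a Pg-metabolism function."""

    code: str
    full_name: str
    role: str
    synonyms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.role not in (SYNTHESIS, CATABOLISM):
            raise ValueError(f"{self.code}: unknown role {self.role!r}")
        if not self.synonyms:
            raise ValueError(f"{self.code}: empty synonym list")


def _parse_vocabulary_text(text: str, origin: str) -> list[EnzymeFunction]:
    entries: list[EnzymeFunction] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if ln == 1 and line.startswith("code\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{origin}: line {ln}: expected 4 columns")
        code, full_name, role, synonyms = parts
        entries.append(
            EnzymeFunction(
                code=code,
                full_name=full_name,
                role=role,
                synonyms=tuple(s for s in synonyms.split("|") if s),
            )
        )
    _validate(entries, origin)
    return entries


def _validate(entries: list[EnzymeFunction], origin: str) -> None:
    codes = [e.code for e in entries]
    if len(codes) != len(set(codes)):
        raise ValueError(f"{origin}: duplicate function codes")
    claimed: dict[str, str] = {}
    for e in entries:
        for syn in e.synonyms:
            key = syn.lower()
            if key in claimed and claimed[key] != e.code:
                raise ValueError(
                    f"{origin}: synonym {syn!r} claimed by both "
                    f"{claimed[key]} and {e.code}"
                )
            claimed[key] = e.code


def load_vocabulary(path: str | Path | None = None) -> list[EnzymeFunction]:
    """Load an enzyme vocabulary from a TSV file, or the built-in default.

    The TSV columns are ``code``, ``full_name``, ``role``
    (``synthesis``/``catabolism``) and a pipe-separated synonym list.
    A synonym claimed by two codes is fatal.
    """
    if path is None:
        text = (
            resources.files("pgmine.data")
            .joinpath("pg_enzyme_vocabulary.tsv")
            .read_text()
        )
        return _parse_vocabulary_text(text, "builtin vocabulary")
    path = Path(path)
    return _parse_vocabulary_text(path.read_text(), path.name)
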