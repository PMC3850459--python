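"""Turn hospital encounter records into a weighted term-by-encounter matrix.

Every encounter contributes field-qualified terms: one per ICD-9-CM code in
each coded field (``adm:`` admitting diagnosis, ``sec:`` secondary
diagnosis, ``prin:`` principal diagnosis, ``pproc:``/``sproc:``
principal/secondary procedure), a ``gender:`` and ``disch:`` term, a binned
``age:`` term, and stop-word-filtered ``txt:`` tokens from any free text.
Qualifying terms by field keeps the clinical role of a code: the same
diagnosis code means different things as an admitting complaint versus a
principal diagnosis.

The matrix is terms x encounters with entries 0/1 (binary), raw counts
(tf), or counts scaled by ``ln(N / df)`` (tfidf, the default).  tf-idf
downweights terms shared by nearly every encounter (e.g. "discharged home"),
which is what lets norm-driven factorizations latch onto diagnostic
structure rather than ubiquitous demographics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "EncounterRecord",
    "TermVocabulary",
    "TermEncounterMatrix",
    "tokenize_encounter",
    "build_matrix",
    "load_stoplist",
    "FIELD_PREFIXES",
]

# prefix -> human-readable field name (report order mirrors the clinical table)
FIELD_PREFIXES = {
    "adm": "admitting diagnoses",
    "sec": "secondary diagnoses",
    "prin": "principal diagnoses",
    "pproc": "principal procedures",
    "sproc": "secondary procedures",
    "age": "age (year)",
    "gender": "gender",
    "disch": "discharge status",
    "txt": "free text",
}

_MISSING = {"", "n/a", "na", "none", "unknown"}


def _norm_code(code: str) -> Optional[str]:
    code = str(code).strip().lower()
    return None if code in _MISSING else code


@dataclass
class EncounterRecord:
    """One hospital encounter: demographics plus ICD-9-CM / APR-DRG coding."""

    encounter_id: str
    patient_id: str
    gender: str                      # male / female / unknown
    age_years: float
    discharge_status: str
    apr_drg: int
    admitting_dx: list = field(default_factory=list)
    secondary_dx: list = field(default_factory=list)
    principal_dx: list = field(default_factory=list)
    principal_proc: Optional[str] = None
    secondary_procs: list = field(default_factory=list)
    free_text: Optional[str] = None

    def __post_init__(self) -> None:
        self.gender = str(self.gender).strip().lower() or "unknown"
        if self.gender not in ("male", "female", "unknown"):
            raise ValueError(f"unrecognized gender {self.gender!r}")
        self.age_years = float(self.age_years)
        if not 0 <= self.age_years < 22:
            raise ValueError(
                f"age {self.age_years} outside the pediatric range [0, 22)")
        self.apr_drg = int(self.apr_drg)


@dataclass
class TermVocabulary:
    """Ordered, field-qualified term list with a term -> row index map."""

    terms: list

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("vocabulary terms must be unique")
        self.index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index


@dataclass
class TermEncounterMatrix:
    """Weighted term-by-encounter matrix (M terms x N encounters)."""

    matrix: np.ndarray
    vocabulary: TermVocabulary
    encounter_ids: list
    weighting: str
    idf: Optional[np.ndarray] = None  # set for tfidf; reusable for projection


def load_stoplist(source=None) -> set:
    """Load a stop-word set (lower-cased, deduplicated).

    With no argument the bundled English list is used.  Stop words apply
    only to free-text tokens, never to code-valued fields.
    """
    if source is None:
        text = (resources.files("phenofactor") / "data" /
                "stopwords_en.txt").read_text()
    else:
        text = Path(source).read_text()
    return {line.strip().lower() for line in text.splitlines() if line.strip()}


def tokenize_encounter(record: EncounterRecord, age_bin_width: float = 0.5,
                       stoplist: Optional[set] = None) -> list:
    """Emit the field-qualified terms of one encounter.

    Missing / "N/A" fields emit nothing.  The age term covers the half-open
    bin ``[b, b + width)`` with ``b`` a multiple of ``age_bin_width``.
    """
    stoplist = stoplist or set()
    terms = []
    for prefix, codes in (("adm", record.admitting_dx),
                          ("sec", record.secondary_dx),
                          ("prin", record.principal_dx),
                          ("pproc", [record.principal_proc]
                                    if record.principal_proc else []),
                          ("sproc", record.secondary_procs)):
        for code in codes:
            c = _norm_code(code) if code is not None else None
            if c is not None:
                terms.append(f"{prefix}:{c}")
    if record.gender != "unknown":
        terms.append(f"gender:{record.gender}")
    disch = _norm_code(record.discharge_status)
    if disch is not None:
        terms.append(f"disch:{disch}")
    b = math.floor(record.age_years / age_bin_width) * age_bin_width
    terms.append(f"age:{b:g}-{b + age_bin_width:g}")
    if record.free_text:
        for tok in record.free_text.lower().split():
            if tok and tok not in stoplist:
                terms.append(f"txt:{tok}")
    return terms


def build_matrix(records: Sequence[EncounterRecord], weighting: str = "tfidf",
                 age_bin_width: float = 0.5, stoplist: Optional[set] = None,
                 vocabulary: Optional[TermVocabulary] = None,
                 idf: Optional[np.ndarray] = None,
                 drop_empty: bool = True) -> TermEncounterMatrix:
    """Assemble the weighted term-by-encounter matrix.

    When ``vocabulary`` is supplied (e.g. projecting test encounters through
    a training vocabulary) unseen terms are dropped, guaranteeing the output
    lives in the training row space; pass the training ``idf`` as well so
    tf-idf test columns use training document frequencies.  With
    ``drop_empty=False`` token-less encounters are kept as all-zero columns
    (needed so every test encounter receives a score).
    """
    if len(records) == 0:
        raise ValueError("no encounter records supplied")
    if weighting not in ("binary", "tf", "tfidf"):
        raise ValueError(f"unknown weighting {weighting!r}")

    token_lists, kept = [], []
    for rec in records:
        toks = tokenize_encounter(rec, age_bin_width=age_bin_width,
                                  stoplist=stoplist)
        if vocabulary is not None:
            toks = [t for t in toks if t in vocabulary]
        if toks or not drop_empty:
            token_lists.append(toks)
            kept.append(rec.encounter_id)
        else:
            warnings.warn(f"encounter {rec.encounter_id} has no tokens and "
                          "was dropped", stacklevel=2)

    if vocabulary is None:
        seen = sorted({t for toks in token_lists for t in toks})
        if not seen:
            raise ValueError("empty vocabulary: no tokens in any encounter")
        vocabulary = TermVocabulary(seen)

    M, N = len(vocabulary), len(token_lists)
    counts = np.zeros((M, N))
    for j, toks in enumerate(token_lists):
        for t in toks:
            counts[vocabulary.index[t], j] += 1.0

    if weighting == "binary":
        mat, idf_out = (counts > 0).astype(float), None
    elif weighting == "tf":
        mat, idf_out = counts, None
    else:
        if idf is None:
            df = (counts > 0).sum(axis=1)
            with np.errstate(divide="ignore"):
                idf = np.where(df > 0, np.log(N / np.maximum(df, 1)), 0.0)
        idf_out = np.asarray(idf, dtype=float)
        if idf_out.shape != (M,):
            raise ValueError("idf length does not match the vocabulary")
        mat = counts * idf_out[:, None]

    return TermEncounterMatrix(mat, vocabulary, kept, weighting, idf_out)
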