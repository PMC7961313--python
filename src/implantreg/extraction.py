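"""Turn raw surgery rows into typed procedures.

Three primitives, each configurable through :class:`~implantreg.config.PipelineConfig`:

* :func:`classify_procedure` — CPT-code based typing (primary / revision /
  removal / other) with priority removal > revision > primary > other;
* :func:`parse_side` — keyword/regex side parsing of the scheduled-procedure
  and post-op diagnosis free text, conservative on conflicts;
* :func:`clean_part_number` — strip extraneous characters from the raw
  prosthesis-model field to recover a cleanable part number. Letter case is
  preserved deliberately: case handling belongs to the catalog lookup layer,
  where a case-insensitive fallback can be audited (or switched off).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .config import PipelineConfig

TYPE_PRIORITY = ["removal", "revision", "primary", "other"]

#: characters a cleaned part number may contain
_PN_CHARS = re.compile(r"[^A-Za-z0-9\-./]")
_PARENS = re.compile(r"\([^)]*\)")


@dataclass
class TypedProcedure:
    surgery_id: object
    patient_id: str
    surgery_date: object
    procedure_type: str
    side: str
    cleaned_part_numbers: list


def classify_procedure(cpt_codes, code_map=None) -> str:
    """Classify a surgery from its CPT codes.

    Returns the highest-priority type among the mapped codes, with priority
    removal > revision > primary > other. Unrecognized codes map to other;
    an empty code list is other.
    """
    if code_map is None:
        code_map = PipelineConfig().code_map
    types = {code_map.get(str(c).strip(), "other") for c in cpt_codes}
    for t in TYPE_PRIORITY:
        if t in types:
            return t
    return "other"


def _find_sides(text: str, cfg: PipelineConfig) -> set:
    found = set()
    if not text:
        return found
    up = text.upper()
    for pat in cfg.bilateral_tokens:
        if re.search(pat, up):
            return {"left", "right"}
    for pat in cfg.left_tokens:
        if re.search(pat, up):
            found.add("left")
            break
    for pat in cfg.right_tokens:
        if re.search(pat, up):
            found.add("right")
            break
    return found


def parse_side(scheduled_procedure_text: str, principal_postop_diagnosis_text: str,
               config: PipelineConfig | None = None) -> str:
    """Parse the surgical side from free text.

    The scheduled-procedure field is authoritative; the diagnosis field is the
    fallback when it is silent. Conflicting or bilateral indicators in one
    field yield ``unknown`` rather than a guess.
    """
    cfg = config or PipelineConfig()
    primary = _find_sides(scheduled_procedure_text or "", cfg)
    if len(primary) == 1:
        return primary.pop()
    if len(primary) > 1:
        return "unknown"
    fallback = _find_sides(principal_postop_diagnosis_text or "", cfg)
    if len(fallback) == 1:
        return fallback.pop()
    return "unknown"


def clean_part_number(raw: str, config: PipelineConfig | None = None) -> str:
    """Strip extraneous characters from a raw prosthesis-model entry.

    Removes parenthesized fragments, strips leading/trailing catalog-noise
    tokens (REF, LOT, ``#``, ``*``), drops characters outside
    ``[A-Za-z0-9-./]`` and returns the result with case preserved. An empty
    result is the missing-value sentinel (empty string). Idempotent.
    """
    cfg = config or PipelineConfig()
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return ""
    s = _PARENS.sub(" ", str(raw)).strip()
    strip_set = {t.upper() for t in cfg.strip_tokens}
    tokens = s.split()

    def is_noise(tok: str) -> bool:
        t = tok.upper()
        return t in strip_set or all(ch in "#*" for ch in t)

    while tokens and is_noise(tokens[0]):
        tokens.pop(0)
    while tokens and is_noise(tokens[-1]):
        tokens.pop()
    s = " ".join(tokens)
    s = _PN_CHARS.sub("", s)
    return s


def extract_procedures(surgeries: pd.DataFrame,
                       config: PipelineConfig | None = None) -> pd.DataFrame:
    """Apply typing, side parsing and part-number cleaning to a surgery table.

    Expects the columns written by the generator / EHR export: ``surgery_id``,
    ``patient_id``, ``surgery_date``, ``cpt_codes`` (``;``-joined),
    ``scheduled_procedure_text``, ``principal_postop_diagnosis_text``,
    ``prosthesis_model_entries`` (``|``-joined raw strings).

    Returns one row per surgery with ``procedure_type``, ``side`` and the
    cleaned part-number list (``cleaned_part_numbers``, aligned with
    ``raw_part_entries`` — missing numbers are kept as empty strings so entry
    indices stay stable for auditing).
    """
    cfg = config or PipelineConfig()
    rows = []
    for r in surgeries.itertuples(index=False):
        codes = [c for c in str(r.cpt_codes).split(";") if c]
        raw_entries = ([] if (pd.isna(r.prosthesis_model_entries)
                              or r.prosthesis_model_entries == "")
                       else str(r.prosthesis_model_entries).split("|"))
        sched = "" if pd.isna(r.scheduled_procedure_text) else r.scheduled_procedure_text
        diag = ("" if pd.isna(r.principal_postop_diagnosis_text)
                else r.principal_postop_diagnosis_text)
        rows.append({
            "surgery_id": r.surgery_id,
            "patient_id": r.patient_id,
            "surgery_date": r.surgery_date,
            "procedure_type": classify_procedure(codes, cfg.code_map),
            "side": parse_side(sched, diag, cfg),
            "raw_part_entries": raw_entries,
            "cleaned_part_numbers": [clean_part_number(e, cfg) for e in raw_entries],
        })
    return pd.DataFrame(rows)


def typed_to_csv(typed: pd.DataFrame, path) -> None:
    out = typed.copy()
    out["raw_part_entries"] = out.raw_part_entries.map(lambda v: "|".join(v))
    out["cleaned_part_numbers"] = out.cleaned_part_numbers.map(lambda v: "|".join(v))
    out.to_csv(path, index=False)


def typed_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    for col in ("raw_part_entries", "cleaned_part_numbers"):
        df[col] = df[col].map(lambda v: v.split("|") if v else [])
    return df
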