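"""Resolve cleaned part numbers against a GUDID-like device catalog.

The catalog is a file contract: a CSV with columns ``part_number, company,
brand, size, category_term, material``. Three override maps layer on top
(see :class:`~implantreg.config.CatalogOverrides`): enrichment rows for
legacy parts, component-class overrides for models whose category term is
wrong, and model-aggregation overrides where the first-6-characters rule
fails.

Lookup order: exact part-number match, then (if enabled) a case-insensitive
fallback — entered part numbers frequently differ from catalog case — then
the enrichment list. Anything else is ``not_in_catalog``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .config import CatalogOverrides, PipelineConfig

log = logging.getLogger(__name__)

MAJOR_CLASSES = ("shell", "liner", "stem", "head")

#: category-term fragments -> component class; checked in order, first hit wins
DEFAULT_TERM_RULES = [
    ("MONOBLOCK", "shell"),
    ("SHELL", "shell"),
    ("CUP", "shell"),
    ("LINER", "liner"),
    ("INSERT", "liner"),
    ("STEM", "stem"),
    ("HEAD", "head"),
    ("BALL", "head"),
]


@dataclass
class CatalogEntry:
    part_number: str
    company: str
    brand_model: str
    size: str
    category_term: str
    material: str
    component_class: str = ""

    @property
    def is_major(self) -> bool:
        return self.component_class in MAJOR_CLASSES

    @property
    def is_monoblock(self) -> bool:
        return "MONOBLOCK" in str(self.category_term).upper()


@dataclass
class MappingResult:
    cleaned: str
    status: str            # mapped | not_in_catalog | ambiguous
    entry: Optional[CatalogEntry]
    match_mode: str = ""   # exact | case_insensitive | override


class Catalog:
    """Indexed view of the catalog CSV plus overrides."""

    def __init__(self, table: pd.DataFrame, overrides: CatalogOverrides | None = None):
        if table.part_number.duplicated().any():
            dups = table.part_number[table.part_number.duplicated()].tolist()
            raise ValueError(f"duplicate part numbers in catalog: {dups[:5]}")
        self.table = table.reset_index(drop=True)
        self.overrides = overrides or CatalogOverrides()
        self._exact = {r.part_number: i for i, r in enumerate(table.itertuples(index=False))}
        self._folded: dict[str, list[int]] = {}
        for pn, i in self._exact.items():
            self._folded.setdefault(pn.upper(), []).append(i)
        self._enrich = {str(e["part_number"]): e for e in self.overrides.enrichment}

    @classmethod
    def from_csv(cls, path, overrides: CatalogOverrides | None = None) -> "Catalog":
        return cls(pd.read_csv(path, dtype=str, keep_default_na=False), overrides)

    def _entry(self, i: int) -> CatalogEntry:
        r = self.table.iloc[i]
        return CatalogEntry(r.part_number, r.company, r.brand, str(r["size"]),
                            r.category_term, r.material)


def lookup_part(cleaned: str, catalog: Catalog,
                config: PipelineConfig | None = None) -> MappingResult:
    """Map a cleaned part number to a catalog entry.

    Exact match first; else a case-insensitive fallback (recorded in
    ``match_mode`` so case repairs stay auditable; disable with
    ``case_insensitive_fallback=False``); else the enrichment override list;
    else ``not_in_catalog``. Multiple case-insensitive candidates are
    ``ambiguous`` and logged.
    """
    cfg = config or PipelineConfig()
    if not cleaned:
        raise ValueError("lookup_part requires a non-missing cleaned part number")
    i = catalog._exact.get(cleaned)
    if i is not None:
        return MappingResult(cleaned, "mapped", catalog._entry(i), "exact")
    if cfg.case_insensitive_fallback:
        cands = catalog._folded.get(cleaned.upper(), [])
        if len(cands) == 1:
            return MappingResult(cleaned, "mapped", catalog._entry(cands[0]),
                                 "case_insensitive")
        if len(cands) > 1:
            log.warning("ambiguous case-insensitive match for %r (%d candidates)",
                        cleaned, len(cands))
            return MappingResult(cleaned, "ambiguous", None, "")
    e = catalog._enrich.get(cleaned) or catalog._enrich.get(cleaned.upper())
    if e is not None:
        entry = CatalogEntry(
            part_number=str(e["part_number"]), company=e.get("company", ""),
            brand_model=e.get("brand", ""), size=str(e.get("size", "")),
            category_term=e.get("category_term", ""), material=e.get("material", "other"))
        return MappingResult(cleaned, "mapped", entry, "override")
    return MappingResult(cleaned, "not_in_catalog", None, "")


def classify_component(entry: CatalogEntry, overrides: CatalogOverrides | None = None,
                       prefix_length: int = 6) -> str:
    """Assign the component class (shell/liner/stem/head/minor) to an entry.

    The device-category term decides by default; a class override keyed by the
    model prefix supersedes it (for models whose catalog term is wrong —
    e.g. a stem categorized as a femoral head). Unknown category terms demote
    to ``minor`` with a log line: a missed major part is a false negative
    downstream, never a silent false positive.
    """
    ov = overrides or CatalogOverrides()
    prefix = entry.part_number[:prefix_length]
    forced = ov.class_overrides.get(entry.part_number) or ov.class_overrides.get(prefix)
    if forced:
        return forced
    term = str(entry.category_term).upper()
    for frag, cls in DEFAULT_TERM_RULES:
        if frag in term:
            return cls
    log.info("unknown category term %r for %s -> classified minor",
             entry.category_term, entry.part_number)
    return "minor"


def aggregate_model(part_number: str, overrides: CatalogOverrides | None = None,
                    prefix_length: int = 6) -> str:
    """Aggregate a sized part number into its model key.

    Default rule: the first ``prefix_length`` characters. An aggregation
    override (exact part number, else prefix) takes precedence. Numbers
    shorter than the prefix length aggregate to themselves, with a warning —
    truncated entries are a real failure mode worth surfacing.
    """
    ov = overrides or CatalogOverrides()
    if not part_number:
        raise ValueError("aggregate_model requires a non-missing part number")
    if part_number in ov.aggregation_overrides:
        return ov.aggregation_overrides[part_number]
    prefix = part_number[:prefix_length]
    if prefix in ov.aggregation_overrides:
        return ov.aggregation_overrides[prefix]
    if len(part_number) < prefix_length:
        log.warning("part number %r shorter than model prefix length %d",
                    part_number, prefix_length)
        return part_number
    return prefix


def map_parts(typed: pd.DataFrame, catalog: Catalog,
              config: PipelineConfig | None = None) -> pd.DataFrame:
    """Map every cleaned part entry of a typed-procedure table.

    Returns one row per (surgery, entry index): cleaned string, mapping
    status/mode, and — for mapped entries — company, category term, material,
    component class and model key.
    """
    cfg = config or PipelineConfig()
    rows = []
    for r in typed.itertuples(index=False):
        for j, cleaned in enumerate(r.cleaned_part_numbers):
            base = {"surgery_id": r.surgery_id, "patient_id": r.patient_id,
                    "surgery_date": r.surgery_date, "entry_index": j,
                    "cleaned": cleaned}
            if not cleaned:
                rows.append({**base, "status": "missing", "match_mode": "",
                             "part_number": "", "component_class": "",
                             "model_key": "", "material": "", "is_major": False,
                             "is_monoblock": False})
                continue
            res = lookup_part(cleaned, catalog, cfg)
            if res.status != "mapped":
                rows.append({**base, "status": res.status, "match_mode": res.match_mode,
                             "part_number": "", "component_class": "",
                             "model_key": "", "material": "", "is_major": False,
                             "is_monoblock": False})
                continue
            e = res.entry
            cls = classify_component(e, cfg.overrides, cfg.model_prefix_length)
            e.component_class = cls
            rows.append({**base, "status": "mapped", "match_mode": res.match_mode,
                         "part_number": e.part_number, "component_class": cls,
                         "model_key": aggregate_model(e.part_number, cfg.overrides,
                                                      cfg.model_prefix_length),
                         "material": e.material,
                         "is_major": cls in MAJOR_CLASSES,
                         "is_monoblock": e.is_monoblock})
    cols = ["surgery_id", "patient_id", "surgery_date", "entry_index", "cleaned",
            "status", "match_mode", "part_number", "component_class", "model_key",
            "material", "is_major", "is_monoblock"]
    return pd.DataFrame(rows, columns=cols)
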