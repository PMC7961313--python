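"""Synthetic EHR generator with known ground truth.

Emulates the statistical structure an EHR-to-implant-registry pipeline
confronts in a large integrated health system:

* a device catalog in a GUDID-like layout (part number, company, brand, size,
  device-category term, material), with model families sharing a 6-character
  part-number prefix across sizes, plus "legacy" models that are used in
  surgeries but absent from the catalog;
* primary total-hip-arthroplasty surgeries placing a shell, liner, stem and
  femoral head (or a monoblock shell covering shell+head), with optional
  minor parts (screws, hole plugs);
* per-model Weibull component failures that trigger revision surgeries
  replacing the failed component (and, with configured probability, its
  articulating mate), tracked through revisions of revisions;
* censoring by death, end of study, and out-of-system revision (the patient
  leaves the system before an unobserved failure — no revision record, and
  the encounter stream stops);
* per-part data-entry corruption of the free-text prosthesis-model field:
  missing entry, entry written into the wrong surgical record, excess
  characters, a wrong (catalog-absent) number, legacy part substitution, and
  letter-case flips.

Every generated part and component is recorded in ground-truth tables, so the
downstream pipeline can be scored exactly.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import CatalogOverrides, ErrorRates, SimulationConfig

DAYS_PER_YEAR = 365.25

PN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"

#: articulating mate of each component class (replaced together with
#: probability ``mate_replacement_prob``)
MATE = {"shell": "liner", "liner": "shell", "stem": "head", "head": "stem"}

CATEGORY_TERMS = {
    "shell": "HIP ACETABULAR SHELL",
    "monoblock": "HIP ACETABULAR SHELL MONOBLOCK",
    "liner": "HIP ACETABULAR LINER",
    "stem": "HIP FEMORAL STEM",
    "head_metal": "HIP FEMORAL HEAD METAL",
    "head_ceramic": "HIP FEMORAL HEAD CERAMIC",
    "screw": "BONE SCREW",
    "plug": "HOLE PLUG",
}

SIZE_CODES = {
    "shell": ["48", "50", "52", "54", "56", "58", "60", "62", "64", "66"],
    "liner": ["28", "32", "36", "40", "44", "48", "52", "56", "60", "64"],
    "stem": ["10", "11", "12", "13", "14", "15", "16", "17", "18", "19"],
    "head": ["28", "32", "36", "40", "44", "48", "52", "56", "60", "64"],
    "minor": ["04", "06", "08", "10", "12", "14", "16", "18", "20", "22"],
}

COMPANIES = [
    "Atlas Orthopaedics", "Borealis Implants", "Cumberland Medical",
    "Delta Joint Systems", "Evergreen Ortho", "Foxglove Surgical",
]

SCHEDULED_TEMPLATES = [
    "{SIDE} TOTAL HIP ARTHROPLASTY",
    "{ST} THA",
    "TOTAL HIP REPLACEMENT {SIDE}",
    "{SIDE} HIP ARTHROPLASTY REVISION",
]
DIAGNOSIS_TEMPLATES = [
    "OSTEOARTHRITIS {side} HIP",
    "DJD {side} HIP",
    "",
]
SIDE_TOKENS = {"left": ("LEFT", "LT"), "right": ("RIGHT", "RT")}

EXCESS_PREFIXES = ["REF ", "REF# ", "* ", "LOT ", "  "]
EXCESS_SUFFIXES = [" *", " REF", " (LOT)", "  ", " #"]


# ---------------------------------------------------------------------------
# Catalog


@dataclass
class SyntheticCatalog:
    """Catalog plus generation truth.

    ``catalog`` is the public GUDID-like table the pipeline sees. ``legacy``
    holds the sized entries of legacy models (absent from ``catalog``).
    ``models`` has one row per model family with its truth attributes.
    ``overrides`` are the hand-curated corrections a registry maintainer
    would supply (here: class overrides for miscategorized models).
    """

    catalog: pd.DataFrame
    legacy: pd.DataFrame
    models: pd.DataFrame
    overrides: CatalogOverrides
    all_part_numbers: set = field(default_factory=set)


def _model_keys(prefix2: str, n: int, start: int = 1) -> list[str]:
    return [f"{prefix2}{i:04d}" for i in range(start, start + n)]


def generate_catalog(config: SimulationConfig) -> SyntheticCatalog:
    """Build the synthetic device catalog and its ground-truth model table.

    Model families get a 6-character key (e.g. ``SH0003``); sized part numbers
    append a size code (``SH0003-52``). A ``legacy_fraction`` of each class's
    models is excluded from the public catalog. The last
    ``miscategorized_stem_models`` stems carry a femoral-head category term in
    the catalog (their corrective class override is returned alongside), and
    the last ``monoblock_shell_models`` shells are monoblock (one part number
    covering shell + head).
    """
    rows = []
    class_specs = [
        ("shell", "SH", config.n_models.get("shell", 0), "metal"),
        ("liner", "LN", config.n_models.get("liner", 0), "poly"),
        ("stem", "ST", config.n_models.get("stem", 0), "metal"),
        ("head", "HM", config.n_models.get("head_metal", 0), "metal"),
        ("head", "HC", config.n_models.get("head_ceramic", 0), "ceramic"),
        ("minor", "MP", config.n_models.get("minor", 0), "other"),
    ]
    for cls, prefix, n, mat in class_specs:
        if n == 0:
            continue
        n_legacy = math.ceil(config.legacy_fraction * n) if config.legacy_fraction > 0 else 0
        n_legacy = min(n_legacy, max(n - 1, 0))  # keep at least one current model
        keys = _model_keys(prefix, n)
        for i, key in enumerate(keys):
            is_legacy = i >= n - n_legacy
            rows.append({
                "model_key": key,
                "component_class": cls,
                "material": mat,
                "prefix_group": prefix,
                "is_legacy": is_legacy,
                "is_monoblock": False,
                "miscategorized": False,
                "company": COMPANIES[i % len(COMPANIES)],
                "brand": f"{key} {cls.title()}",
            })
    models = pd.DataFrame(rows)

    # monoblock shells: last non-legacy shells
    shells = models.index[(models.component_class == "shell") & ~models.is_legacy]
    for idx in shells[len(shells) - config.monoblock_shell_models:]:
        models.loc[idx, "is_monoblock"] = True
        models.loc[idx, "material"] = "metal"

    # miscategorized stems: last non-legacy stems carry a head category term
    stems = models.index[(models.component_class == "stem") & ~models.is_legacy]
    class_overrides = {}
    for idx in stems[len(stems) - config.miscategorized_stem_models:]:
        models.loc[idx, "miscategorized"] = True
        class_overrides[models.loc[idx, "model_key"]] = "stem"

    # usage weights within each (class, material) pool, Zipf-like
    conc = config.model_usage_concentration
    models["usage_weight"] = 0.0
    for (cls, mat, legacy), grp in models.groupby(
            ["component_class", "material", "is_legacy"]):
        ranks = np.arange(1, len(grp) + 1, dtype=float)
        w = ranks ** (-conc) if conc > 0 else np.ones_like(ranks)
        models.loc[grp.index, "usage_weight"] = w / w.sum()

    # sized entries
    sized = []
    for _, m in models.iterrows():
        cls = m.component_class
        sizes = SIZE_CODES["head" if cls == "head" else
                           "minor" if cls == "minor" else cls][: config.sizes_per_model]
        if m.component_class == "head":
            term = CATEGORY_TERMS["head_metal" if m.material == "metal" else "head_ceramic"]
        elif m.is_monoblock:
            term = CATEGORY_TERMS["monoblock"]
        elif m.miscategorized:
            term = CATEGORY_TERMS["head_metal"]  # wrong on purpose
        elif cls == "minor":
            term = CATEGORY_TERMS["screw"] if int(m.model_key[2:]) % 2 else CATEGORY_TERMS["plug"]
        else:
            term = CATEGORY_TERMS[cls]
        for size in sizes:
            sized.append({
                "part_number": f"{m.model_key}-{size}",
                "company": m.company,
                "brand": m.brand,
                "size": size,
                "category_term": term,
                "material": m.material,
                "model_key": m.model_key,
                "is_legacy": m.is_legacy,
            })
    sized = pd.DataFrame(sized)
    public_cols = ["part_number", "company", "brand", "size", "category_term", "material"]
    catalog = sized.loc[~sized.is_legacy, public_cols].reset_index(drop=True)
    legacy = sized.loc[sized.is_legacy, public_cols + ["model_key"]].reset_index(drop=True)
    return SyntheticCatalog(
        catalog=catalog,
        legacy=legacy,
        models=models,
        overrides=CatalogOverrides(class_overrides=class_overrides),
        all_part_numbers=set(sized.part_number),
    )


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class SyntheticCohort:
    """One generated EHR: public tables plus ground truth."""

    surgeries: pd.DataFrame      # EHR view: free text, CPT codes, part entries
    encounters: pd.DataFrame     # patient_id, encounter_date
    deaths: pd.DataFrame         # patient_id, death_date
    gt_surgeries: pd.DataFrame   # surgery_id -> true type/side
    gt_components: pd.DataFrame  # one row per implanted major component
    gt_parts: pd.DataFrame       # one row per part record (major + minor)
    config: SimulationConfig


class _ModelPools:
    """Pre-indexed model pools and attribute dicts for fast draws."""

    def __init__(self, models: pd.DataFrame, sizes_per_model: int):
        self.pools = {}
        for (cls, mat, legacy), grp in models.groupby(
                ["component_class", "material", "is_legacy"]):
            self.pools[(cls, mat, bool(legacy))] = (
                grp.model_key.to_numpy(), grp.usage_weight.to_numpy(),
                grp.is_monoblock.to_numpy())
        self.class_pools = {}
        for (cls, legacy), grp in models.groupby(["component_class", "is_legacy"]):
            self.class_pools[(cls, bool(legacy))] = (
                grp.model_key.to_numpy(),
                (grp.usage_weight / grp.usage_weight.sum()).to_numpy(),
                grp.is_monoblock.to_numpy())
        self.info = {m.model_key: (m.component_class, m.material,
                                   bool(m.is_monoblock), bool(m.is_legacy))
                     for m in models.itertuples(index=False)}
        self.sizes = {}
        for mk, (cls, _, _, _) in self.info.items():
            key = "head" if cls == "head" else "minor" if cls == "minor" else cls
            self.sizes[mk] = SIZE_CODES[key][:sizes_per_model]

    def draw(self, rng, cls, n=1, material=None, legacy=False):
        key = (cls, material, legacy) if material is not None else None
        if key is not None and key in self.pools:
            keys, w, _ = self.pools[key]
            w = w / w.sum()
        else:
            keys, w, _ = self.class_pools[(cls, legacy)]
        return rng.choice(keys, size=n, p=w)

    def has_legacy(self, cls):
        return (cls, True) in self.class_pools


def _hazard_params(config: SimulationConfig, model_key: str) -> tuple[float, float]:
    hz = config.model_hazards.get(model_key)
    shape = config.weibull_shape
    scale_rel = 1.0
    if hz is not None:
        scale_rel = hz.scale_rel
        if hz.shape is not None:
            shape = hz.shape
    return shape, scale_rel


def _calibrate_base_scale(config: SimulationConfig, followup_years: np.ndarray,
                          shapes: np.ndarray, scale_rels: np.ndarray,
                          comp_surgery: np.ndarray) -> float:
    """Solve for the global Weibull scale (years) matching the revision target.

    Finds lam0 such that the expected fraction of primaries with at least one
    component failing inside its true follow-up window equals
    ``revision_fraction / (1 - revision_fraction)`` (so that expected
    revisions / (primaries + revisions) ~= revision_fraction; revision-of-
    revision chains add a small second-order surplus).
    """
    rf = config.revision_fraction
    if rf <= 0:
        return math.inf
    target = rf / (1.0 - rf)
    n_surg = int(comp_surgery.max()) + 1

    def mean_fail(log_lam):
        lam = math.exp(log_lam)
        ch = (followup_years / (scale_rels * lam)) ** shapes  # cumulative hazard
        logs = np.zeros(n_surg)
        np.add.at(logs, comp_surgery, -ch)
        return float(np.mean(1.0 - np.exp(logs))) - target

    lo, hi = math.log(1e-3), math.log(1e7)
    if mean_fail(lo) < 0:  # even a tiny scale cannot reach the target
        return 1e-3
    return math.exp(brentq(mean_fail, lo, hi, xtol=1e-10))


def generate_cohort(config: SimulationConfig, cat: SyntheticCatalog) -> SyntheticCohort:
    """Generate surgeries, encounters, deaths and ground truth for one cohort.

    Determinism: identical (config, catalog) pairs produce identical outputs.
    Randomness is split over independent named streams (demographics,
    component assignment, failure times, out-of-system decisions, data-entry
    corruption, encounters), so changing ``out_of_system_revision_rate`` alone
    leaves the underlying failure truth of primary components untouched.
    """
    ss = np.random.SeedSequence(config.seed)
    (s_demo, s_assign, s_fail, s_oos, s_corrupt, s_enc) = ss.spawn(6)
    rng_demo = np.random.default_rng(s_demo)
    rng_assign = np.random.default_rng(s_assign)
    rng_fail = np.random.default_rng(s_fail)
    rng_oos = np.random.default_rng(s_oos)
    rng_corrupt = np.random.default_rng(s_corrupt)
    rng_enc = np.random.default_rng(s_enc)

    pools = _ModelPools(cat.models, config.sizes_per_model)
    info = pools.info
    n = config.n_patients
    years = np.asarray(config.years)
    study_end = np.datetime64(f"{config.year_range[1]}-12-31")

    # --- demographics and primary surgery dates -----------------------------
    yr = rng_demo.choice(years, size=n, p=config.volume_weights())
    day = rng_demo.integers(0, 365, size=n)
    surg_date = (yr - 1970).astype("datetime64[Y]").astype("datetime64[D]") + day
    surg_date = np.minimum(surg_date, study_end)
    male = rng_demo.random(n) < config.male_fraction
    age = np.clip(rng_demo.normal(config.age_mean_sd[0], config.age_mean_sd[1], n), 21, 99)
    side = np.where(rng_demo.random(n) < 0.5, "left", "right")

    # --- death and administrative censoring ---------------------------------
    if config.mortality_rate > 0:
        t_death = rng_demo.exponential(1.0 / config.mortality_rate, size=n)
    else:
        t_death = np.full(n, np.inf)
    death_date = surg_date + np.round(t_death * DAYS_PER_YEAR).astype("timedelta64[D]")
    has_death = death_date <= study_end
    followup_end = np.where(has_death, death_date, study_end)  # truth censor bound

    # --- per-year error rates ------------------------------------------------
    err0 = config.error_rates
    rates_cache = {int(y): config.error_rates_by_year.get(int(y), err0)
                   for y in years}

    def rates_for_year(y: int) -> ErrorRates:
        return rates_cache.get(int(y), err0)

    # --- primary component assignment (vectorized) --------------------------
    ceramic_p = config.ceramic_adoption.ceramic_prob(yr)
    is_ceramic = rng_assign.random(n) < ceramic_p

    shell_models = pools.draw(rng_assign, "shell", n)
    liner_models = pools.draw(rng_assign, "liner", n)
    stem_models = pools.draw(rng_assign, "stem", n)
    head_metal = pools.draw(rng_assign, "head", n, material="metal")
    head_ceramic = pools.draw(rng_assign, "head", n, material="ceramic")
    head_models = np.where(is_ceramic, head_ceramic, head_metal)

    # legacy substitution at assignment time (per component, per-year rate)
    legacy_rates = np.array([rates_cache[int(y)].legacy_part for y in yr])

    def maybe_legacy(model_arr, cls, u):
        out = model_arr.copy()
        hit = u < legacy_rates
        if hit.any() and pools.has_legacy(cls):
            for i in np.nonzero(hit)[0]:
                mat = info[model_arr[i]][1]
                pool = pools.pools.get((cls, mat, True))
                out[i] = (rng_assign.choice(pool[0], p=pool[1] / pool[1].sum())
                          if pool is not None else
                          pools.draw(rng_assign, cls, 1, legacy=True)[0])
        return out

    shell_models = maybe_legacy(shell_models, "shell", rng_assign.random(n))
    liner_models = maybe_legacy(liner_models, "liner", rng_assign.random(n))
    stem_models = maybe_legacy(stem_models, "stem", rng_assign.random(n))
    head_models = maybe_legacy(head_models, "head", rng_assign.random(n))
    shell_mono = np.array([info[mk][2] for mk in shell_models])

    def pick_size(mk, u):
        sizes = pools.sizes[mk]
        return sizes[int(u * len(sizes))]

    # flat arrays of primary components
    comp_patient: list[int] = []
    comp_class: list[str] = []
    comp_model: list[str] = []
    comp_size: list[str] = []
    comp_mono: list[bool] = []
    size_u = rng_assign.random((n, 4))
    for i in range(n):
        entries = [("shell", shell_models[i])]
        if not shell_mono[i]:
            entries += [("liner", liner_models[i]), ("head", head_models[i])]
        entries += [("stem", stem_models[i])]
        for j, (cls, mk) in enumerate(entries):
            comp_patient.append(i)
            comp_class.append(cls)
            comp_model.append(mk)
            comp_size.append(pick_size(mk, size_u[i, j % 4]))
            comp_mono.append(bool(cls == "shell" and shell_mono[i]))
    comp_surgery = np.asarray(comp_patient)
    n_comp = len(comp_surgery)

    followup_years = (
        (followup_end[comp_surgery] - surg_date[comp_surgery])
        .astype("timedelta64[D]").astype(float) / DAYS_PER_YEAR)

    hz_cache = {mk: _hazard_params(config, mk) for mk in info}
    shapes = np.array([hz_cache[mk][0] for mk in comp_model])
    scale_rels = np.array([hz_cache[mk][1] for mk in comp_model])

    lam0 = _calibrate_base_scale(config, followup_years, shapes, scale_rels, comp_surgery)
    if math.isfinite(lam0):
        t_fail_years = scale_rels * lam0 * rng_fail.weibull(shapes)
        fail_days = np.maximum(np.round(t_fail_years * DAYS_PER_YEAR), 1.0)
    else:
        fail_days = np.full(n_comp, np.inf)

    # --- walk failure chains per patient ------------------------------------
    oos_rate = config.out_of_system_revision_rate
    surgeries: list[dict] = []   # surgical events (EHR + truth typing)
    components: list[dict] = []  # ground-truth component episodes
    parts: list[dict] = []       # ground-truth part records (major + minor)
    enc_cut = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")

    comp_by_patient: dict[int, list[int]] = {}
    for k in range(n_comp):
        comp_by_patient.setdefault(int(comp_surgery[k]), []).append(k)

    minor_u = rng_assign.random(n)
    minor_n = rng_assign.integers(1, 3, size=n)
    minor_pool = pools.class_pools.get(("minor", False))
    surg_dates_by_pat: dict[int, list] = {}

    def new_surgery(pid, date, stype):
        sid = len(surgeries)
        surgeries.append({
            "surgery_id": sid, "patient_idx": pid, "surgery_date": date,
            "true_type": stype,
        })
        surg_dates_by_pat.setdefault(pid, []).append(date)
        return sid

    def add_component(pid, sid, date, cls, mk, size, monoblock):
        cid = len(components)
        pn = f"{mk}-{size}"
        is_leg = info[mk][3]
        components.append({
            "component_id": cid, "patient_idx": pid, "surgery_id": sid,
            "implant_date": date, "component_class": cls, "model_key": mk,
            "part_number": pn, "size": size, "is_monoblock": monoblock,
            "is_legacy": is_leg,
            "true_end_date": None, "true_end_reason": "",
            "removal_surgery_id": -1,
        })
        parts.append({
            "component_id": cid, "surgery_id": sid, "patient_idx": pid,
            "component_class": cls, "part_number": pn,
            "model_key": mk, "is_legacy": is_leg,
            "year": date.astype("datetime64[Y]").astype(int) + 1970,
        })
        return cid

    def draw_component(cls, date):
        y = int(date.astype("datetime64[Y]").astype(int)) + 1970
        if cls == "head":
            pc = float(config.ceramic_adoption.ceramic_prob(y))
            mat = "ceramic" if rng_assign.random() < pc else "metal"
            mk = pools.draw(rng_assign, "head", 1, material=mat)[0]
        elif cls == "shell":
            # revisions use modular shells
            keys, w, mono = pools.class_pools[("shell", False)]
            ok = ~mono
            ww = w[ok] / w[ok].sum() if ok.any() else w
            mk = rng_assign.choice(keys[ok] if ok.any() else keys, p=ww)
        else:
            mk = pools.draw(rng_assign, cls, 1)[0]
        if rng_assign.random() < rates_for_year(y).legacy_part and pools.has_legacy(cls):
            mk = pools.draw(rng_assign, cls, 1, legacy=True)[0]
        return mk, pick_size(mk, rng_assign.random())

    def close(cid, date, reason, rsid):
        row = components[cid]
        row["true_end_date"] = date
        row["true_end_reason"] = reason
        row["removal_surgery_id"] = rsid

    for pid in range(n):
        p_date = surg_date[pid]
        sid = new_surgery(pid, p_date, "primary")
        active: dict[int, dict] = {}
        heap: list[tuple[int, int]] = []
        for k in comp_by_patient[pid]:
            cid = add_component(pid, sid, p_date, comp_class[k], comp_model[k],
                                comp_size[k], comp_mono[k])
            cls_set = {"shell", "head"} if comp_mono[k] else {comp_class[k]}
            f = fail_days[k]
            fdate = p_date + np.timedelta64(int(f), "D") if np.isfinite(f) else None
            active[cid] = {"classes": cls_set, "fail": fdate}
            if fdate is not None and fdate <= followup_end[pid]:
                heapq.heappush(heap, (fdate.astype(int), cid))
        # minor parts on the primary
        if minor_pool is not None and minor_u[pid] < config.minor_parts_prob:
            for _ in range(int(minor_n[pid])):
                mk = rng_assign.choice(minor_pool[0], p=minor_pool[1])
                parts.append({
                    "component_id": -1, "surgery_id": sid, "patient_idx": pid,
                    "component_class": "minor",
                    "part_number": f"{mk}-{pick_size(mk, rng_assign.random())}",
                    "model_key": mk, "is_legacy": info[mk][3],
                    "year": int(yr[pid]),
                })

        while heap:
            fint, cid = heapq.heappop(heap)
            if cid not in active:
                continue
            fdate = np.datetime64(int(fint), "D")
            if rng_oos.random() < oos_rate:
                # failure revised outside the system: encounters stop before it
                enc_cut[pid] = fdate
                close(cid, fdate, "failed_out_of_system", -1)
                del active[cid]
                for ocid in list(active):
                    of = active[ocid]["fail"]
                    if of is not None and of <= followup_end[pid]:
                        close(ocid, of, "failed_out_of_system", -1)
                        del active[ocid]
                break
            if rng_assign.random() < config.removal_fraction:
                rsid = new_surgery(pid, fdate, "removal")
                for ocid in list(active):
                    close(ocid, fdate,
                          "failed" if ocid == cid else "removed_incidental", rsid)
                    del active[ocid]
                break
            # revision replacing the failed component (+ possibly its mate)
            rsid = new_surgery(pid, fdate, "revision")
            removed = set(active[cid]["classes"])
            in_situ_classes = {c for st in active.values() for c in st["classes"]}
            for c in list(removed):
                m = MATE.get(c)
                if (m and m in in_situ_classes and m not in removed
                        and rng_assign.random() < config.mate_replacement_prob):
                    removed.add(m)
            for ocid in list(active):
                if active[ocid]["classes"] & removed:
                    removed |= active[ocid]["classes"]  # monoblock drags both classes
                    close(ocid, fdate,
                          "failed" if ocid == cid else "removed_incidental", rsid)
                    del active[ocid]
            for c in sorted(removed):
                mk, size = draw_component(c, fdate)
                ncid = add_component(pid, rsid, fdate, c, mk, size, False)
                shp, srel = hz_cache[mk]
                t = srel * lam0 * rng_fail.weibull(shp) if math.isfinite(lam0) else math.inf
                nf = (fdate + np.timedelta64(max(int(round(t * DAYS_PER_YEAR)), 1), "D")
                      if math.isfinite(t) else None)
                active[ncid] = {"classes": {c}, "fail": nf}
                if nf is not None and nf <= followup_end[pid]:
                    heapq.heappush(heap, (nf.astype(int), ncid))

    # --- encounters ----------------------------------------------------------
    enc_pat: list[int] = []
    enc_date: list = []
    last_enc: dict[int, np.datetime64] = {}
    mean_gap = config.encounter_gap_mean
    for pid in range(n):
        end = followup_end[pid]
        if not np.isnat(enc_cut[pid]):
            end = min(end, enc_cut[pid] - np.timedelta64(1, "D"))
        dates = {d for d in surg_dates_by_pat.get(pid, []) if d <= end}
        span = int((end - surg_date[pid]).astype(int))
        if span > 0:
            k = max(int(span / mean_gap * 1.6) + 4, 4)
            gaps = np.maximum(np.round(rng_enc.exponential(mean_gap, size=k)), 1)
            offs = np.cumsum(gaps)
            while offs[-1] <= span:  # rare: extend until the window is covered
                gaps = np.maximum(np.round(rng_enc.exponential(mean_gap, size=k)), 1)
                offs = np.concatenate([offs, offs[-1] + np.cumsum(gaps)])
            offs = offs[offs <= span]
            dates.update(surg_date[pid] + offs.astype("timedelta64[D]"))
        if not dates:
            dates = {surg_date[pid]}
        sdates = sorted(dates)
        enc_pat.extend([pid] * len(sdates))
        enc_date.extend(sdates)
        last_enc[pid] = sdates[-1]
    encounters = pd.DataFrame({"patient_idx": enc_pat, "encounter_date": enc_date})

    # --- resolve censored component truth ------------------------------------
    for row in components:
        if row["true_end_reason"]:
            continue
        pid = row["patient_idx"]
        if has_death[pid] and np.isnat(enc_cut[pid]):
            row["true_end_date"] = death_date[pid]
            row["true_end_reason"] = "censored_dead"
        else:
            row["true_end_date"] = max(last_enc[pid], row["implant_date"])
            row["true_end_reason"] = "censored_alive"

    # --- data-entry corruption of part records --------------------------------
    parts_df = pd.DataFrame(parts)
    m = len(parts_df)
    yrs = parts_df.year.to_numpy()
    rate = {name: np.array([getattr(rates_for_year(y), name) for y in yrs])
            for name in ["missing_part", "wrong_record", "excess_chars",
                         "wrong_digits", "case_flip"]}
    u = rng_corrupt.random((m, 5))
    f_missing = u[:, 0] < rate["missing_part"]
    f_wrongrec = (~f_missing) & (u[:, 1] < rate["wrong_record"])
    f_wrongdig = (~f_missing) & (u[:, 2] < rate["wrong_digits"])
    f_case = (~f_missing) & (u[:, 3] < rate["case_flip"])
    f_excess = (~f_missing) & (u[:, 4] < rate["excess_chars"])

    universe = cat.all_part_numbers
    texts = parts_df.part_number.tolist()
    for i in np.nonzero(f_wrongdig)[0]:
        s = texts[i]
        for _ in range(20):
            pos = int(rng_corrupt.integers(0, len(s)))
            if s[pos] == "-":
                continue
            repl = PN_ALPHABET[int(rng_corrupt.integers(0, len(PN_ALPHABET)))]
            if repl == s[pos]:
                continue
            cand = s[:pos] + repl + s[pos + 1:]
            if cand not in universe:
                s = cand
                break
        texts[i] = s
    for i in np.nonzero(f_case)[0]:
        texts[i] = texts[i].swapcase()
    pre_idx = rng_corrupt.integers(0, len(EXCESS_PREFIXES), size=m)
    suf_idx = rng_corrupt.integers(0, len(EXCESS_SUFFIXES), size=m)
    for i in np.nonzero(f_excess)[0]:
        texts[i] = EXCESS_PREFIXES[pre_idx[i]] + texts[i] + EXCESS_SUFFIXES[suf_idx[i]]

    n_surg = len(surgeries)
    target = parts_df.surgery_id.to_numpy().copy()
    if n_surg > 1:
        shift = rng_corrupt.integers(1, n_surg, size=m)
        target[f_wrongrec] = (target[f_wrongrec] + shift[f_wrongrec]) % n_surg

    parts_df["corrupt_missing"] = f_missing
    parts_df["corrupt_wrong_record"] = f_wrongrec
    parts_df["corrupt_wrong_digits"] = f_wrongdig
    parts_df["corrupt_case_flip"] = f_case
    parts_df["corrupt_excess_chars"] = f_excess
    parts_df["entry_text"] = texts
    parts_df["entry_surgery_id"] = np.where(f_missing, -1, target)

    # assemble per-surgery entry lists; own entries first, strays appended
    entry_lists: list[list[str]] = [[] for _ in range(n_surg)]
    entry_index = np.full(m, -1)
    own = (~f_missing) & (~f_wrongrec)
    for i in np.nonzero(own)[0]:
        sid = target[i]
        entry_index[i] = len(entry_lists[sid])
        entry_lists[sid].append(texts[i])
    for i in np.nonzero(f_wrongrec)[0]:
        sid = target[i]
        entry_index[i] = len(entry_lists[sid])
        entry_lists[sid].append(texts[i])
    parts_df["entry_index"] = entry_index

    # --- EHR surgery table ----------------------------------------------------
    surg_df = pd.DataFrame(surgeries)
    tmpl_i = rng_demo.integers(0, len(SCHEDULED_TEMPLATES), size=n_surg)
    diag_i = rng_demo.integers(0, len(DIAGNOSIS_TEMPLATES), size=n_surg)
    extra_code = rng_demo.random(n_surg) < 0.3
    rev_codes = rng_demo.choice(["27134", "27137", "27138"], size=n_surg)
    prim_codes = rng_demo.choice(["27130", "27132"], size=n_surg, p=[0.9, 0.1])
    rem_codes = rng_demo.choice(["27090", "27091"], size=n_surg)

    sched, diag, cpts = [], [], []
    for j, row in enumerate(surgeries):
        s = side[row["patient_idx"]]
        full, abbr = SIDE_TOKENS[s]
        sched.append(SCHEDULED_TEMPLATES[tmpl_i[j]].format(SIDE=full, ST=abbr))
        diag.append(DIAGNOSIS_TEMPLATES[diag_i[j]].format(side=full))
        code = {"primary": prim_codes[j], "revision": rev_codes[j],
                "removal": rem_codes[j]}[row["true_type"]]
        cpts.append(";".join([code] + (["99213"] if extra_code[j] else [])))

    patient_ids = np.array([f"P{pid:06d}" for pid in range(n)])
    pidx = surg_df.patient_idx.to_numpy()
    surgeries_out = pd.DataFrame({
        "surgery_id": surg_df.surgery_id,
        "patient_id": patient_ids[pidx],
        "surgery_date": pd.to_datetime(surg_df.surgery_date).dt.strftime("%Y-%m-%d"),
        "cpt_codes": cpts,
        "scheduled_procedure_text": sched,
        "principal_postop_diagnosis_text": diag,
        "prosthesis_model_entries": ["|".join(e) for e in entry_lists],
    })

    gt_surgeries = pd.DataFrame({
        "surgery_id": surg_df.surgery_id,
        "patient_id": patient_ids[pidx],
        "true_type": surg_df.true_type,
        "true_side": side[pidx],
        "surgery_date": pd.to_datetime(surg_df.surgery_date).dt.strftime("%Y-%m-%d"),
        "patient_male": male[pidx],
        "patient_age": np.round(age[pidx], 1),
    })

    comp_df = pd.DataFrame(components)
    comp_df["patient_id"] = patient_ids[comp_df.patient_idx]
    comp_df["side"] = side[comp_df.patient_idx.to_numpy()]
    comp_df["implant_date"] = pd.to_datetime(comp_df.implant_date).dt.strftime("%Y-%m-%d")
    comp_df["true_end_date"] = pd.to_datetime(comp_df.true_end_date).dt.strftime("%Y-%m-%d")
    gt_components = comp_df.drop(columns=["patient_idx"])

    parts_df["patient_id"] = patient_ids[parts_df.patient_idx]
    gt_parts = parts_df.drop(columns=["patient_idx"])

    encounters_out = pd.DataFrame({
        "patient_id": patient_ids[encounters.patient_idx],
        "encounter_date": pd.to_datetime(encounters.encounter_date).dt.strftime("%Y-%m-%d"),
    })
    deaths_out = pd.DataFrame({
        "patient_id": patient_ids[np.nonzero(has_death)[0]],
        "death_date": pd.to_datetime(death_date[has_death]).strftime("%Y-%m-%d"),
    })

    return SyntheticCohort(
        surgeries=surgeries_out, encounters=encounters_out, deaths=deaths_out,
        gt_surgeries=gt_surgeries, gt_components=gt_components, gt_parts=gt_parts,
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, cat: SyntheticCatalog, outdir) -> dict:
    """Write the cohort and catalog as RFC-4180 CSVs; returns path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, df in [
        ("surgeries", cohort.surgeries), ("encounters", cohort.encounters),
        ("deaths", cohort.deaths), ("catalog", cat.catalog),
        ("ground_truth_surgeries", cohort.gt_surgeries),
        ("ground_truth_components", cohort.gt_components),
        ("ground_truth_parts", cohort.gt_parts),
    ]:
        p = os.path.join(outdir, f"{name}.csv")
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
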