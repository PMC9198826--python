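"""Synthetic inpatient cohorts with the statistical structure the model assumes.

The real training corpus (inpatient charts from a TCM hospital) is
proprietary, so this module generates cohorts that emulate its structure:
each patient carries 1-3 latent syndromes; each syndrome emits its own
symptom tokens and the patient accumulates time-stamped vitals/labs over the
stay; at each order time the physician prescribes, per target first-category,
one uniformly chosen leaf drug of that category — so two draws of the same
patient's prescription may differ in leaf ids while agreeing after category
rollup, exactly the substitution behaviour the rollup metric is designed for.

Noise controls: ``label_noise`` swaps a target category for a random other
one per order; ``symptom_noise`` injects spurious symptoms from other
syndromes; ``qc_corrupt_frac`` plants chart-quality defects of the four
discard kinds so the QC filter has something to find.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .features import SPECIAL_CIRCUMSTANCES, ClinicalFact, Order, PatientRecord
from .ontology import DrugNode, DrugOntology

__all__ = ["CohortConfig", "SyndromeRule", "generate_ontology", "make_syndrome_rules",
           "generate_cohort", "corrupt_records", "ORDER_TIMES_HOURS"]

ORDER_TIMES_HOURS = (0.0, 24.0, 48.0, 72.0, 168.0)

_VITALS = [
    ("temperature", "celsius"), ("heart_rate", "bpm"), ("resp_rate", "perminute"),
    ("bp_systolic", "mmhg"), ("bp_diastolic", "mmhg"),
]
_LABS = [
    ("wbc", "e9perl"), ("rbc", "e12perl"), ("hemoglobin", "gperl"),
    ("glucose", "mmolperl"), ("alt", "uperl"), ("ast", "uperl"),
    ("creatinine", "umolperl"), ("crp", "mgperl"),
]
_BINS = ("low", "normal", "high")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``admission_symptom_frac`` controls how much of each syndrome's symptom
    evidence is already present at admission; the remainder surfaces at
    uniform times over the stay, which is what makes later prediction
    cutoffs better informed than earlier ones.
    """

    n_patients: int = 500
    n_syndromes: int = 10
    n_category1: int = 10
    leaves_per_category: int = 5
    symptoms_per_syndrome: int = 6
    categories_per_syndrome: int = 3
    syndromes_per_patient: tuple[int, int] = (1, 3)
    facts_per_day: float = 1.0
    horizon_days: int = 7
    admission_symptom_frac: float = 1.0
    symptom_time_dist: str = "uniform"  # or "per_interval" (clustered around
    # order-review times so each successive order slice gains fresh evidence)
    shared_symptom_frac: float = 0.0  # fraction of each syndrome's symptoms
    # drawn from a common pool of nonspecific complaints; these surface first,
    # so admission evidence is ambiguous and discriminative findings accrue
    label_noise: float = 0.0
    symptom_noise: float = 0.0
    qc_corrupt_frac: float = 0.0
    category_dist: str = "uniform"  # or "zipf"
    seed: int = 0

    def __post_init__(self):
        for name in ("label_noise", "symptom_noise", "qc_corrupt_frac",
                     "admission_symptom_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_patients", "n_syndromes", "n_category1",
                     "leaves_per_category", "symptoms_per_syndrome",
                     "categories_per_syndrome", "horizon_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class SyndromeRule:
    syndrome_id: str
    emitted_symptom_tokens: frozenset[str]
    target_categories: frozenset[str]

    def __post_init__(self):
        if not self.emitted_symptom_tokens or not self.target_categories:
            raise ValueError("syndrome rule needs non-empty symptom and category sets")


def generate_ontology(cfg: CohortConfig) -> DrugOntology:
    """Three-level hierarchy: each first category has one category-II node
    carrying ``leaves_per_category`` leaf drugs."""
    nodes: list[DrugNode] = []
    for c in range(cfg.n_category1):
        cat1 = f"cat1_{c:03d}"
        cat2 = f"cat2_{c:03d}"
        nodes.append(DrugNode(cat1, f"category_{c:03d}", "category1", None))
        nodes.append(DrugNode(cat2, f"formula_{c:03d}", "category2", cat1))
        for l in range(cfg.leaves_per_category):
            nodes.append(
                DrugNode(f"leaf_{c:03d}_{l:02d}", f"herb_{c:03d}_{l:02d}", "leaf", cat2)
            )
    return DrugOntology(nodes)


def make_syndrome_rules(cfg: CohortConfig, onto: DrugOntology) -> list[SyndromeRule]:
    """Planted diagnosis->treatment rules.

    Each syndrome owns ``symptoms_per_syndrome`` unique symptom tokens (its
    evidence is unambiguous) and targets a distinct primary category plus
    ``categories_per_syndrome - 1`` secondary ones, so the syndrome->category
    map is injective and the planted rule is identifiable from symptoms.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    cats = onto.category1_ids()
    if cfg.n_syndromes > len(cats):
        raise ValueError("need n_category1 >= n_syndromes for injective primaries")
    n_shared = int(round(cfg.shared_symptom_frac * cfg.symptoms_per_syndrome))
    pool = [f"symptom_shared_{k:02d}" for k in range(2 * max(n_shared, 1))]
    rules = []
    for s in range(cfg.n_syndromes):
        symptoms = {
            f"symptom_{s:02d}_{k:02d}"
            for k in range(cfg.symptoms_per_syndrome - n_shared)
        }
        if n_shared:
            symptoms |= set(rng.choice(pool, size=n_shared, replace=False))
        symptoms = frozenset(symptoms)
        primary = cats[s]
        others = [c for c in cats if c != primary]
        n_extra = min(cfg.categories_per_syndrome - 1, len(others))
        extra = rng.choice(others, size=n_extra, replace=False) if n_extra else []
        rules.append(
            SyndromeRule(
                syndrome_id=f"syndrome_{s:02d}",
                emitted_symptom_tokens=symptoms,
                target_categories=frozenset([primary, *extra]),
            )
        )
    return rules


def _emit_symptom_fact(name: str, t: float) -> ClinicalFact:
    section = "chief_complaints" if t == 0.0 else "treatment_process"
    return ClinicalFact(t_hours=float(t), section=section, name=name)


def _background_facts(rng: np.random.Generator, cfg: CohortConfig) -> list[ClinicalFact]:
    horizon_h = cfg.horizon_days * 24.0
    n = rng.poisson(cfg.facts_per_day * cfg.horizon_days)
    facts = []
    # an admission vitals check anchors every chart at t=0
    for name, unit in _VITALS[:2]:
        facts.append(ClinicalFact(0.0, "body_check", name, "normal", unit))
    for _ in range(n):
        t = float(rng.uniform(0.0, horizon_h))
        if rng.random() < 0.5:
            name, unit = _VITALS[rng.integers(len(_VITALS))]
            section = "nursing_notes"
        else:
            name, unit = _LABS[rng.integers(len(_LABS))]
            section = "laboratory_reports"
        value = _BINS[rng.choice(3, p=[0.15, 0.7, 0.15])]
        facts.append(ClinicalFact(t, section, name, value, unit))
    return facts


def _patient_category_weights(cfg: CohortConfig, n: int) -> np.ndarray:
    if cfg.category_dist == "uniform":
        return np.full(n, 1.0 / n)
    if cfg.category_dist == "zipf":
        w = 1.0 / np.arange(1, n + 1)
        return w / w.sum()
    raise ValueError(f"unknown category_dist {cfg.category_dist!r}")


def generate_cohort(
    cfg: CohortConfig,
    onto: DrugOntology,
    rules: list[SyndromeRule] | None = None,
) -> list[PatientRecord]:
    """Draw ``n_patients`` records; deterministic for a fixed config seed."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    if rules is None:
        rules = make_syndrome_rules(cfg, onto)
    cats = onto.category1_ids()
    horizon_h = cfg.horizon_days * 24.0
    order_times = [t for t in ORDER_TIMES_HOURS if t <= horizon_h]
    syn_weights = _patient_category_weights(cfg, len(rules))
    records: list[PatientRecord] = []
    for p in range(cfg.n_patients):
        lo, hi = cfg.syndromes_per_patient
        k = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(rules), size=min(k, len(rules)), replace=False, p=syn_weights)
        patient_rules = [rules[i] for i in sorted(idx)]
        sex = "female" if rng.random() < 0.5 else "male"
        height = float(rng.normal(168 if sex == "male" else 158, 7))
        weight = float(rng.normal(68 if sex == "male" else 58, 9))
        demo = {
            "sex": sex,
            "age": float(rng.uniform(20, 90)),
            "height": height,
            "weight": weight,
            "bmi": weight / (height / 100) ** 2,
        }
        facts = _background_facts(rng, cfg)
        target_cats: set[str] = set()
        for rule in patient_rules:
            target_cats |= rule.target_categories
            # nonspecific shared complaints surface before syndrome-specific
            # findings: shuffle within each group, emit shared-first
            shared = [s for s in sorted(rule.emitted_symptom_tokens) if "shared" in s]
            unique = [s for s in sorted(rule.emitted_symptom_tokens) if "shared" not in s]
            emission = [shared[i] for i in rng.permutation(len(shared))] + \
                       [unique[i] for i in rng.permutation(len(unique))]
            n_adm = int(round(cfg.admission_symptom_frac * len(emission)))
            n_rem = len(emission) - n_adm
            edges = sorted({*order_times[1:], horizon_h})
            for j, name in enumerate(emission):
                if j < n_adm:
                    t = 0.0
                elif cfg.symptom_time_dist == "per_interval":
                    # spread the remainder evenly across the order intervals,
                    # in emission order, so every later slice gains evidence
                    k_iv = (j - n_adm) * len(edges) // max(n_rem, 1)
                    lo_t = 0.0 if k_iv == 0 else edges[k_iv - 1]
                    t = float(rng.uniform(lo_t, edges[k_iv]))
                else:
                    t = float(rng.uniform(0.0, horizon_h))
                facts.append(_emit_symptom_fact(name, t))
        # spurious symptoms from unassigned syndromes
        if cfg.symptom_noise > 0:
            assigned = {r.syndrome_id for r in patient_rules}
            for rule in rules:
                if rule.syndrome_id in assigned:
                    continue
                for s in sorted(rule.emitted_symptom_tokens):
                    if rng.random() < cfg.symptom_noise:
                        t = float(rng.uniform(0.0, horizon_h))
                        facts.append(_emit_symptom_fact(s, t))
        facts.sort(key=lambda f: (f.t_hours, f.section, f.name))
        orders = []
        for t in order_times:
            drug_ids = []
            for cat in sorted(target_cats):
                if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
                    cat = cats[rng.integers(len(cats))]
                leaves = onto.leaves_of_category(cat)
                drug_ids.append(leaves[rng.integers(len(leaves))] if leaves else cat)
            orders.append(Order(t_hours=t, drug_ids=sorted(set(drug_ids))))
        records.append(
            PatientRecord(
                patient_id=f"patient_{p:05d}",
                demographics=demo,
                facts=facts,
                orders=orders,
                meta={
                    "syndromes": [r.syndrome_id for r in patient_rules],
                    "target_categories": sorted(target_cats),
                },
            )
        )
    return records


# -- QC defect planting ----------------------------------------------------

_DEFECTS = ("incomplete", "inconsistent", "nonstandard", "special_circumstance")


def corrupt_records(records: Iterable[PatientRecord], cfg: CohortConfig) -> list[PatientRecord]:
    """Plant one QC defect (of the four discard kinds) in a Bernoulli
    ``qc_corrupt_frac`` fraction of records; others pass through untouched."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    out: list[PatientRecord] = []
    for r in records:
        if cfg.qc_corrupt_frac == 0.0 or rng.random() >= cfg.qc_corrupt_frac:
            out.append(r)
            continue
        defect = _DEFECTS[rng.integers(len(_DEFECTS))]
        r2 = PatientRecord(
            patient_id=r.patient_id,
            demographics=None if defect == "incomplete" else dict(r.demographics),
            facts=[ClinicalFact(**vars(f)) for f in r.facts],
            orders=[Order(o.t_hours, list(o.drug_ids)) for o in r.orders],
            meta={**r.meta, "planted_defect": defect},
        )
        if defect == "inconsistent":
            src = r2.facts[rng.integers(len(r2.facts))]
            flipped = "high" if src.value != "high" else "low"
            r2.facts.append(
                ClinicalFact(src.t_hours, src.section, src.name, flipped, src.unit)
            )
        elif defect == "nonstandard":
            r2.facts.append(
                ClinicalFact(0.0, "treatment_process", "Freitext@Befund")
            )
        elif defect == "special_circumstance":
            marker = SPECIAL_CIRCUMSTANCES[rng.integers(len(SPECIAL_CIRCUMSTANCES))]
            r2.facts.append(
                ClinicalFact(0.0, "treatment_process", "special_circumstance", marker)
            )
        out.append(r2)
    return out
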