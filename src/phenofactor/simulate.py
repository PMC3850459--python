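"""Seeded synthetic pediatric encounter cohorts with planted phenotypes.

Each cohort mixes a small number of latent phenotype profiles.  The default
set models four pediatric respiratory APR-DRG groups: 141 asthma (the
positive class, built around wheezing on admission, asthma with acute
exacerbation as principal diagnosis, family history of asthma, ages 4-8,
discharged home), and three background groups - 144 respiratory signs &
minor diagnoses, 131 cystic fibrosis with pulmonary disease, 132 BPD &
chronic respiratory disease - with majority-disjoint code sets so the
planted structure is identifiable.

Given a profile, coded fields are emitted independently: admitting /
principal diagnoses and the principal procedure are single categorical
draws; each secondary diagnosis / procedure code is an independent
Bernoulli emission (yielding 0-3 secondary diagnoses per record).  This
conditional independence makes the expected term-by-encounter matrix
exactly low rank - one rank-one term per profile - so factorization methods
have a well-defined ground truth (see :func:`planted_feature_vectors`).
Optional label noise replaces diagnosis codes with uniform draws from the
global code pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import EncounterRecord, TermVocabulary

__all__ = [
    "PhenotypeProfile",
    "SyntheticCohort",
    "default_profiles",
    "generate_cohort",
    "planted_feature_vectors",
    "ASTHMA_APR_DRG",
]

ASTHMA_APR_DRG = 141
_SUM_TOL = 1e-9


def _check_dist(name: str, dist: dict) -> None:
    total = sum(dist.values())
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name} has negative probabilities")


@dataclass
class PhenotypeProfile:
    """Emission model for one latent phenotype.

    ``admitting_dist``, ``principal_dist`` and ``principal_proc_dist`` are
    categorical distributions (one draw per record; the key ``None`` in
    ``principal_proc_dist`` means "no principal procedure").
    ``secondary_emissions`` / ``secondary_proc_emissions`` map codes to
    independent Bernoulli emission probabilities.
    """

    name: str
    apr_drg: int
    prevalence: float
    admitting_dist: dict
    principal_dist: dict
    secondary_emissions: dict = field(default_factory=dict)
    principal_proc_dist: dict = field(default_factory=lambda: {None: 1.0})
    secondary_proc_emissions: dict = field(default_factory=dict)
    age_range: tuple = (0.0, 18.0)
    gender_probs: dict = field(default_factory=lambda: {"male": 0.5,
                                                        "female": 0.5})
    discharge_probs: dict = field(default_factory=lambda: {"home": 1.0})

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        for nm, d in (("admitting_dist", self.admitting_dist),
                      ("principal_dist", self.principal_dist),
                      ("principal_proc_dist", self.principal_proc_dist),
                      ("gender_probs", self.gender_probs),
                      ("discharge_probs", self.discharge_probs)):
            _check_dist(f"{self.name}.{nm}", d)
        lo, hi = self.age_range
        if not 0 <= lo < hi < 22:
            raise ValueError("age_range must satisfy 0 <= low < high < 22")

    def diagnosis_codes(self) -> set:
        return (set(self.admitting_dist) | set(self.principal_dist)
                | set(self.secondary_emissions))


@dataclass
class SyntheticCohort:
    """A generated cohort: records, binary asthma labels, and provenance."""

    records: list
    labels: np.ndarray               # 1 = asthma profile (APR-DRG 141)
    profile_assignments: dict        # encounter_id -> profile name
    seed: int
    noise_rate: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        for rec, lab in zip(self.records, self.labels):
            is_asthma = int(rec.apr_drg == ASTHMA_APR_DRG)
            if lab != is_asthma:
                raise ValueError("labels inconsistent with APR-DRG codes")


def default_profiles(shared_codes: bool = False) -> list:
    """The four respiratory-cohort profiles (prevalences .5/.2/.15/.15).

    With ``shared_codes=True`` some background secondary codes overlap the
    asthma profile, a deliberately harder identifiability stress case.
    """
    asthma = PhenotypeProfile(
        name="asthma", apr_drg=141, prevalence=0.50,
        admitting_dist={"786.07": 0.90, "786.09": 0.05, "786.05": 0.05},
        principal_dist={"493.92": 0.80, "493.90": 0.10, "493.91": 0.10},
        secondary_emissions={"v175": 0.80, "786.05": 0.70, "692.9": 0.60},
        age_range=(4.0, 8.0),
        gender_probs={"male": 0.6, "female": 0.4},
        discharge_probs={"home": 0.95, "transfer": 0.05},
    )
    resp_signs = PhenotypeProfile(
        name="resp_signs", apr_drg=144, prevalence=0.20,
        admitting_dist={"786.2": 0.85, "780.60": 0.15},
        principal_dist={"786.52": 0.75, "786.09": 0.25},
        secondary_emissions={"486.00": 0.80, "079.99": 0.70,
                             **({"786.05": 0.35} if shared_codes else {})},
        age_range=(0.5, 5.0),
        discharge_probs={"home": 0.85, "transfer": 0.15},
    )
    cystic_fibrosis = PhenotypeProfile(
        name="cystic_fibrosis", apr_drg=131, prevalence=0.15,
        admitting_dist={"277.02": 0.90, "799.02": 0.10},
        principal_dist={"277.02": 0.90, "277.09": 0.10},
        secondary_emissions={"482.41": 0.85, "v181": 0.80, "263.9": 0.70,
                             **({"v175": 0.30} if shared_codes else {})},
        age_range=(6.0, 18.0),
        discharge_probs={"home": 0.60, "transfer": 0.25, "snf": 0.15},
    )
    bpd = PhenotypeProfile(
        name="bpd", apr_drg=132, prevalence=0.15,
        admitting_dist={"770.7": 0.85, "786.03": 0.15},
        principal_dist={"770.7": 0.85, "518.81": 0.15},
        secondary_emissions={"765.10": 0.80, "v461": 0.75, "779.31": 0.65},
        age_range=(0.0, 3.0),
        discharge_probs={"home": 0.55, "home_health": 0.30, "transfer": 0.15},
    )
    profiles = [asthma, resp_signs, cystic_fibrosis, bpd]
    total = sum(p.prevalence for p in profiles)
    if abs(total - 1.0) > _SUM_TOL:  # pragma: no cover - construction guard
        raise AssertionError("default prevalences must sum to 1")
    return profiles


def _draw(rng: np.random.Generator, dist: dict):
    keys = list(dist)
    probs = np.array([dist[k] for k in keys])
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def generate_cohort(profiles: Sequence[PhenotypeProfile], n: int,
                    noise_rate: float = 0.0, seed: int = 0) -> SyntheticCohort:
    """Draw ``n`` encounter records from the profile mixture.

    Each record samples a profile by prevalence, then each field
    independently from that profile's distributions.  With probability
    ``noise_rate`` per diagnosis slot (admitting, principal, and each
    emitted secondary code) the code is replaced by a uniform draw from the
    pooled diagnosis codes of all profiles.  All randomness flows from one
    seeded generator, so identical arguments reproduce the cohort exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= noise_rate < 1:
        raise ValueError("noise_rate must lie in [0, 1)")
    prevs = np.array([p.prevalence for p in profiles])
    if len(profiles) == 0 or abs(prevs.sum() - 1.0) > _SUM_TOL:
        raise ValueError("profile prevalences must sum to 1")

    rng = np.random.default_rng(seed)
    code_pool = sorted(set().union(*(p.diagnosis_codes() for p in profiles)))

    def maybe_noise(code: str) -> str:
        if noise_rate > 0 and rng.random() < noise_rate:
            return code_pool[rng.integers(len(code_pool))]
        return code

    records, labels, assignments = [], [], {}
    for i in range(n):
        prof = profiles[rng.choice(len(profiles), p=prevs)]
        secondary = [maybe_noise(c) for c, p in prof.secondary_emissions.items()
                     if rng.random() < p]
        pproc = _draw(rng, prof.principal_proc_dist)
        sprocs = [c for c, p in prof.secondary_proc_emissions.items()
                  if rng.random() < p]
        rec = EncounterRecord(
            encounter_id=f"E{i:05d}",
            patient_id=f"P{i:05d}",
            gender=_draw(rng, prof.gender_probs),
            age_years=float(rng.uniform(*prof.age_range)),
            discharge_status=_draw(rng, prof.discharge_probs),
            apr_drg=prof.apr_drg,
            admitting_dx=[maybe_noise(_draw(rng, prof.admitting_dist))],
            principal_dx=[maybe_noise(_draw(rng, prof.principal_dist))],
            secondary_dx=secondary,
            principal_proc=pproc,
            secondary_procs=sprocs,
        )
        records.append(rec)
        labels.append(int(prof.apr_drg == ASTHMA_APR_DRG))
        assignments[rec.encounter_id] = prof.name
    return SyntheticCohort(records, np.array(labels), assignments,
                           seed=seed, noise_rate=noise_rate)


def planted_feature_vectors(profiles: Sequence[PhenotypeProfile],
                            vocabulary: TermVocabulary,
                            age_bin_width: float = 0.5) -> np.ndarray:
    """Ground-truth feature matrix (M terms x n_profiles).

    Column p is the expected term-indicator vector of profile p under its
    stated emission probabilities (categorical fields contribute their
    emission probability, Bernoulli fields theirs, age bins the uniform
    mass falling in each bin), restricted to the supplied vocabulary and
    l2-normalized.  Used as the oracle in parameter-recovery tests.
    """
    if len(vocabulary) == 0:
        raise ValueError("empty vocabulary")
    F = np.zeros((len(vocabulary), len(profiles)))

    def put(col, term, prob):
        idx = vocabulary.index.get(term)
        if idx is not None:
            F[idx, col] += prob

    for j, prof in enumerate(profiles):
        for code, p in prof.admitting_dist.items():
            put(j, f"adm:{code}", p)
        for code, p in prof.principal_dist.items():
            put(j, f"prin:{code}", p)
        for code, p in prof.secondary_emissions.items():
            put(j, f"sec:{code}", p)
        for code, p in prof.principal_proc_dist.items():
            if code is not None:
                put(j, f"pproc:{code}", p)
        for code, p in prof.secondary_proc_emissions.items():
            put(j, f"sproc:{code}", p)
        for g, p in prof.gender_probs.items():
            put(j, f"gender:{g}", p)
        for d, p in prof.discharge_probs.items():
            put(j, f"disch:{d}", p)
        lo, hi = prof.age_range
        b = np.floor(lo / age_bin_width) * age_bin_width
        while b < hi:
            mass = (min(b + age_bin_width, hi) - max(b, lo)) / (hi - lo)
            put(j, f"age:{b:g}-{b + age_bin_width:g}", mass)
            b += age_bin_width
        norm = np.linalg.norm(F[:, j])
        if norm > 0:
            F[:, j] /= norm
    return F
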