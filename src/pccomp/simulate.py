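"""Synthetic paired-platform cohorts with known ground truth.

The generator emulates the statistical structure of a cross-platform PC
study: each bulk PC sum has a latent per-sample abundance (log-normal with
subject and timepoint effects), constituent abundances are fixed
proportions of it, and the two platforms observe it through their own
efficiency factors and multiplicative log-normal measurement noise.

Design templates mirror the two study layouts the analysis expects:

* a deep multi-timepoint design — few subjects, many timepoints, with
  baseline/intervention pairs around lipid-related challenges;
* a wide cross-sectional design — one sample per subject, with sex and
  disease-group labels.

The per-pair expected ratio q_ij (what composition estimation should
recover) is reported alongside the data:

    E[q_ij] = p_ij · (eff_fa_j / eff_sp_i) · exp((σ_sp² + σ_fa²)/2)

where the last factor is the exact mean of the log-normal noise ratio
(unity when noise is zero).  Fatty-acid efficiencies above the species
efficiency reproduce the "proportion > 1" phenomenon of real platform
comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import ConcentrationMatrix
from .nomenclature import parse_lipid_name
from .reference import ReferenceCompositionTable

LIPID_CHALLENGES = ("FASTING", "PAT", "OLTT")


@dataclass(frozen=True)
class Timepoint:
    name: str
    challenge: Optional[str] = None
    phase: Optional[str] = None  # baseline | intervention


@dataclass
class SumSpec:
    """Ground truth for one PC sum: constituents, proportions, remainder."""

    kit_label: str
    constituents: Tuple[str, ...]
    proportions: Tuple[float, ...]
    remainder_fraction: float
    base_concentration: float = 1.0  # μmol/L scale of the latent sum
    species_efficiency: float = 1.0
    fa_efficiencies: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.constituents) != len(self.proportions):
            raise ValueError(f"{self.kit_label}: constituents/proportions mismatch")
        if not self.fa_efficiencies:
            self.fa_efficiencies = tuple(1.0 for _ in self.constituents)
        if len(self.fa_efficiencies) != len(self.constituents):
            raise ValueError(f"{self.kit_label}: efficiencies mismatch")
        if any(p < 0 for p in self.proportions) or self.remainder_fraction < 0:
            raise ValueError(f"{self.kit_label}: negative proportion")
        total = sum(self.proportions) + self.remainder_fraction
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"{self.kit_label}: proportions + remainder must sum to 1, "
                f"got {total}"
            )
        # normalize all labels to canonical form so outputs match catalogs
        self.kit_label = parse_lipid_name(self.kit_label).label
        self.constituents = tuple(
            parse_lipid_name(c).label for c in self.constituents
        )


@dataclass
class SyntheticConfig:
    sums: List[SumSpec]
    n_subjects: int = 4
    timepoints: List[Timepoint] = field(default_factory=lambda: humet_timepoints())
    cohort: str = "SYNTH"
    sd_subject: float = 0.3  # between-subject SD of log-concentration
    sd_within: float = 0.2  # within-subject (timepoint) SD of log-concentration
    cv_species: float = 0.10  # measurement CV, species-level platform
    cv_fa: float = 0.10  # measurement CV, fatty-acid-level platform
    missing_rate: float = 0.0
    challenge_effects: Dict[str, float] = field(default_factory=dict)
    # multiplier on constituent concentrations at intervention timepoints of
    # the keyed challenge (shifts q, exercising the paired test stage)
    sex_labels: Optional[Sequence[str]] = None
    group_labels: Optional[Sequence[str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or not self.timepoints or not self.sums:
            raise ValueError("need >=1 subject, >=1 timepoint, >=1 sum")
        for name in ("sd_subject", "sd_within", "cv_species", "cv_fa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Latent concentrations and expected ratios behind a simulated cohort."""

    latent_sums: pd.DataFrame  # samples × kit labels, true total abundance
    latent_constituents: pd.DataFrame  # samples × constituent labels
    expected_q: Dict[Tuple[str, str], float]  # (kit label, constituent) -> q


def _noise_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def humet_timepoints(
    n_total: int = 56,
    challenges: Sequence[str] = LIPID_CHALLENGES,
) -> List[Timepoint]:
    """A deep multi-timepoint layout: baseline/intervention per challenge,
    remaining timepoints unlabeled."""
    tps: List[Timepoint] = []
    for ch in challenges:
        tps.append(Timepoint(f"{ch}_baseline", ch, "baseline"))
        tps.append(Timepoint(f"{ch}_intervention", ch, "intervention"))
    for i in range(len(tps) + 1, n_total + 1):
        tps.append(Timepoint(f"t{i:02d}"))
    return tps[:n_total]


def cross_sectional_timepoints() -> List[Timepoint]:
    return [Timepoint("t01")]


def simulate_paired_cohort(
    config: SyntheticConfig,
) -> Tuple[ConcentrationMatrix, ConcentrationMatrix, SyntheticTruth]:
    """Simulate one cohort observed by both platforms.

    Per sum i, subject s, timepoint t the latent abundance is

        T_ist = base_i · exp(u_is + v_ist)

    with u ~ N(0, sd_subject²), v ~ N(0, sd_within²) drawn independently per
    sum.  The species platform observes eff_sp·T·e, the side-chain platform
    observes eff_fa_j·p_ij·T·e per constituent, with e log-normal at the
    platform CV.  Missingness is applied completely at random.  All
    randomness comes from one seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    samples = [
        (s, tp) for s in subjects for tp in config.timepoints
    ]
    sample_ids = [f"{s}_{tp.name}" for s, tp in samples]
    sigma_sp = _noise_sigma(config.cv_species)
    sigma_fa = _noise_sigma(config.cv_fa)
    bias = math.exp((sigma_sp**2 + sigma_fa**2) / 2.0)

    latent_sums: Dict[str, np.ndarray] = {}
    latent_cons: Dict[str, np.ndarray] = {}
    species_obs: Dict[str, np.ndarray] = {}
    fa_obs: Dict[str, np.ndarray] = {}
    expected_q: Dict[Tuple[str, str], float] = {}

    n = len(samples)
    for spec in config.sums:
        u = rng.normal(0.0, config.sd_subject, size=len(subjects))
        u_by_subject = dict(zip(subjects, u))
        v = rng.normal(0.0, config.sd_within, size=n)
        latent = np.array(
            [
                spec.base_concentration * math.exp(u_by_subject[s] + v[k])
                for k, (s, _) in enumerate(samples)
            ]
        )
        latent_sums[spec.kit_label] = latent
        e_sp = np.exp(rng.normal(0.0, sigma_sp, size=n)) if sigma_sp else np.ones(n)
        species_obs[spec.kit_label] = spec.species_efficiency * latent * e_sp
        for j, (constituent, p_ij, eff_fa) in enumerate(
            zip(spec.constituents, spec.proportions, spec.fa_efficiencies)
        ):
            shift = np.ones(n)
            for k, (_, tp) in enumerate(samples):
                if (
                    tp.phase == "intervention"
                    and tp.challenge in config.challenge_effects
                ):
                    shift[k] = config.challenge_effects[tp.challenge]
            true_c = p_ij * latent * shift
            latent_cons[constituent] = true_c
            e_fa = (
                np.exp(rng.normal(0.0, sigma_fa, size=n)) if sigma_fa else np.ones(n)
            )
            fa_obs[constituent] = eff_fa * true_c * e_fa
            expected_q[(spec.kit_label, constituent)] = (
                p_ij * eff_fa / spec.species_efficiency * bias
            )

    species_df = pd.DataFrame(species_obs, index=sample_ids)
    fa_df = pd.DataFrame(fa_obs, index=sample_ids)
    if config.missing_rate > 0:
        species_df = species_df.mask(
            rng.random(species_df.shape) < config.missing_rate
        )
        fa_df = fa_df.mask(rng.random(fa_df.shape) < config.missing_rate)

    sex = None
    stride = 1
    if config.sex_labels is not None:
        pool = list(config.sex_labels)
        sex = {s: pool[i % len(pool)] for i, s in enumerate(subjects)}
        stride = len(pool)  # cross group labels against sex, not alias them
    group = None
    if config.group_labels is not None:
        pool = list(config.group_labels)
        group = {s: pool[(i // stride) % len(pool)] for i, s in enumerate(subjects)}
    meta = pd.DataFrame(
        {
            "subject": [s for s, _ in samples],
            "timepoint": [tp.name for _, tp in samples],
            "cohort": config.cohort,
            "challenge": [tp.challenge for _, tp in samples],
            "phase": [tp.phase for _, tp in samples],
            "sex": [sex[s] if sex else pd.NA for s, _ in samples],
            "group": [group[s] if group else pd.NA for s, _ in samples],
            "run_day": pd.NA,
        },
        index=sample_ids,
    )
    species_cm = ConcentrationMatrix(species_df, meta.copy(), "species_level_kit")
    fa_cm = ConcentrationMatrix(fa_df, meta.copy(), "fatty_acid_level")
    truth = SyntheticTruth(
        latent_sums=pd.DataFrame(latent_sums, index=sample_ids),
        latent_constituents=pd.DataFrame(latent_cons, index=sample_ids),
        expected_q=expected_q,
    )
    return species_cm, fa_cm, truth


def config_from_reference(
    table: ReferenceCompositionTable,
    seed: int = 0,
    **overrides,
) -> SyntheticConfig:
    """Build generator truth whose expected q equals the reference table's.

    Sums whose printed proportions total ≤ 0.9 use them directly as true
    proportions with the rest as unmeasured remainder; larger totals are
    rescaled to 0.9 with remainder 0.1 and the excess moved into the
    fatty-acid platform efficiency (Σq/0.9), so the expected ratios still
    reproduce the printed values — including totals above 1 — while true
    proportions plus remainder sum to one.
    """
    sums: List[SumSpec] = []
    for kit_label in table.sum_labels:
        q = table.proportions(kit_label)
        constituents = tuple(q)
        qv = np.array([q[c] for c in constituents], dtype=float)
        total = float(qv.sum())
        if total <= 0.9:
            p = qv
            remainder = 1.0 - total
            eff = np.ones_like(qv)
        else:
            p = 0.9 * qv / total
            remainder = 0.1
            eff = np.full_like(qv, total / 0.9)
        sums.append(
            SumSpec(
                kit_label=kit_label,
                constituents=constituents,
                proportions=tuple(float(x) for x in p),
                remainder_fraction=float(remainder),
                fa_efficiencies=tuple(float(x) for x in eff),
            )
        )
    return SyntheticConfig(sums=sums, seed=seed, **overrides)


def default_humet_config(
    table: ReferenceCompositionTable, seed: int = 0, **overrides
) -> SyntheticConfig:
    """Deep multi-timepoint design: 4 subjects × 56 timepoints."""
    params = dict(n_subjects=4, timepoints=humet_timepoints(), cohort="HUMET")
    params.update(overrides)
    return config_from_reference(table, seed=seed, **params)


def default_qmdiab_config(
    table: ReferenceCompositionTable, seed: int = 0, **overrides
) -> SyntheticConfig:
    """Wide cross-sectional design: 305 subjects, one sample each, with sex
    and diabetes-group labels."""
    params = dict(
        n_subjects=305,
        timepoints=cross_sectional_timepoints(),
        cohort="QMDIAB",
        sex_labels=("male", "female"),
        group_labels=("control", "diabetic"),
    )
    params.update(overrides)
    return config_from_reference(table, seed=seed, **params)
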