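"""Synthetic cohort generator.

Emulates the statistical structure of a biobank-scale CNV association study:
rare recurrent CNVs at defined loci with recurrent breakpoint categories and
noisy quality scores, binary diseases arising from a logistic model with
covariate and CNV effects under one of four gene-dosage mechanisms, ages of
onset from a Weibull proportional-hazards model, and BMI as an optional
mediator on the CNV -> disease path.

The generator produces the same tabular artifacts a real study would consume
(CNV call table, probe map, phenotype table) so every downstream stage can be
exercised without access-restricted data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._util import child_rng

logger = logging.getLogger(__name__)

MECHANISMS = ("mirror", "ushape", "duponly", "delonly")

#: default fraction of calls drawn with |QS| <= 0.5 (low quality); free
#: parameter of the generator, not an empirical estimate.
DEFAULT_QS_NOISE = 0.2

#: probability that a carrier's CNV has atypical (non-category) breakpoints.
ATYPICAL_PROB = 0.05

#: Weibull baseline shape for ages of onset; scale calibrated so the median
#: baseline onset is ~65 years (right-skewed, late-onset diseases).
WEIBULL_SHAPE = 4.0
WEIBULL_MEDIAN = 65.0
WEIBULL_SCALE = WEIBULL_MEDIAN / np.log(2.0) ** (1.0 / WEIBULL_SHAPE)

#: administrative censoring date for controls.
DEFAULT_CUTOFF = date(2021, 9, 30)

#: reference date at which the "age" covariate is measured (cohort baseline).
BASELINE_DATE = date(2008, 6, 15)


@dataclass(frozen=True)
class BreakpointCategory:
    """A recurrent start/end configuration of CNVs at a locus."""

    start: int
    end: int
    weight: float = 1.0


@dataclass(frozen=True)
class CnvLocus:
    """A locus harboring rare recurrent CNVs.

    Coordinates are 1-based inclusive. ``dup_freq``/``del_freq`` are carrier
    fractions in [0, 0.05] (rare, recurrent CNVs); ``qs_noise`` is the
    fraction of calls drawn with |QS| <= 0.5.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    dup_freq: float = 0.0
    del_freq: float = 0.0
    categories: tuple[BreakpointCategory, ...] = ()
    qs_noise: float = DEFAULT_QS_NOISE

    def __post_init__(self):
        if not (0.0 <= self.dup_freq <= 0.05 and 0.0 <= self.del_freq <= 0.05):
            raise ValueError(
                f"locus {self.locus_id}: dup_freq/del_freq must lie in [0, 0.05]"
            )
        if self.end < self.start:
            raise ValueError(f"locus {self.locus_id}: end < start")
        cats = self.categories or (BreakpointCategory(self.start, self.end, 1.0),)
        for c in cats:
            if c.start < self.start or c.end > self.end:
                raise ValueError(
                    f"locus {self.locus_id}: category [{c.start}, {c.end}] "
                    f"not nested in locus interval"
                )
        w = sum(c.weight for c in cats)
        if not np.isclose(w, 1.0):
            raise ValueError(f"locus {self.locus_id}: category weights sum to {w}, not 1")
        if not (0.0 <= self.qs_noise <= 1.0):
            raise ValueError(f"locus {self.locus_id}: qs_noise outside [0, 1]")

    @property
    def effective_categories(self) -> tuple[BreakpointCategory, ...]:
        return self.categories or (BreakpointCategory(self.start, self.end, 1.0),)


@dataclass(frozen=True)
class GenomeModel:
    """Probe landscape and CNV loci of the simulated genome.

    ``chromosomes`` maps name -> length (bp); ``probes`` maps name -> sorted
    1-based probe positions.
    """

    chromosomes: dict[str, int]
    probes: dict[str, np.ndarray]
    loci: tuple[CnvLocus, ...] = ()

    def __post_init__(self):
        for chrom, pos in self.probes.items():
            if chrom not in self.chromosomes:
                raise ValueError(f"probes on unknown chromosome {chrom}")
            pos = np.asarray(pos)
            if len(pos) and not np.all(np.diff(pos) > 0):
                raise ValueError(f"probe positions not strictly increasing on {chrom}")
            if len(pos) and (pos[0] < 1 or pos[-1] > self.chromosomes[chrom]):
                raise ValueError(f"probe positions outside chromosome {chrom} bounds")
        for locus in self.loci:
            if locus.chrom not in self.chromosomes:
                raise ValueError(f"locus {locus.locus_id} on unknown chromosome")
            if locus.start < 1 or locus.end > self.chromosomes[locus.chrom]:
                raise ValueError(f"locus {locus.locus_id} outside chromosome bounds")
        # overlapping loci on one chromosome make per-locus carrier sampling
        # ambiguous: reject the configuration outright.
        by_chrom: dict[str, list[CnvLocus]] = {}
        for locus in self.loci:
            by_chrom.setdefault(locus.chrom, []).append(locus)
        for chrom, loci in by_chrom.items():
            loci = sorted(loci, key=lambda l: l.start)
            for a, b in zip(loci, loci[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"loci {a.locus_id} and {b.locus_id} overlap on {chrom}"
                    )

    def probe_table(self) -> pd.DataFrame:
        """Probe map as a (probe_id, chrom, pos) frame sorted by (chrom, pos)."""
        rows = []
        for chrom in self.chromosomes:
            for pos in np.asarray(self.probes.get(chrom, ())):
                rows.append((f"probe_{chrom}_{int(pos)}", chrom, int(pos)))
        return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])

    def locus(self, locus_id: str) -> CnvLocus:
        for locus in self.loci:
            if locus.locus_id == locus_id:
                return locus
        raise KeyError(locus_id)


@dataclass(frozen=True)
class EffectSpec:
    """Effect of one locus on one disease under a chosen dosage mechanism.

    ``log_odds`` acts per encoded dosage unit on the liability scale,
    ``hazard_ratio`` multiplies the onset hazard per encoded unit, and
    ``bmi_shift`` moves standardized BMI per encoded unit (mediated path).
    """

    disease: str
    locus_id: str
    mechanism: str
    log_odds: float = 0.0
    hazard_ratio: float = 1.0
    bmi_shift: float = 0.0

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")


@dataclass(frozen=True)
class CovariateSpec:
    """Distributions and liability effects of the simulated covariates.

    Marginals loosely match a middle-aged population biobank: age uniform on
    [40, 70] years at baseline, 54% female, 10% on the secondary genotyping
    array, PCs standard normal.
    """

    n_pcs: int = 4
    age_log_odds: float = 0.04
    sex_log_odds: float = 0.2
    array_log_odds: float = 0.0
    pc_log_odds: float = 0.0
    bmi_log_odds: float = 0.0
    excluded_fraction: float = 0.02
    cutoff: date = DEFAULT_CUTOFF


def simulate_calls(
    genome: GenomeModel,
    n_samples: int,
    seed: int,
    atypical_prob: float = ATYPICAL_PROB,
) -> pd.DataFrame:
    """Draw a CNV call table from the genome model.

    Each sample carries at most one CNV per locus; carriers are drawn
    per-locus at ``dup_freq``/``del_freq``. Breakpoints follow the locus'
    recurrent categories except for an ``atypical_prob`` minority with random
    breakpoints inside the locus. QS sign encodes CNV type; a ``qs_noise``
    fraction of calls has |QS| <= 0.5 (low confidence).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = child_rng(seed, "calls")
    rows: list[tuple] = []
    for locus in genome.loci:
        u = rng.random(n_samples)
        is_dup = u < locus.dup_freq
        is_del = (~is_dup) & (u < locus.dup_freq + locus.del_freq)
        carriers = np.flatnonzero(is_dup | is_del)
        cats = locus.effective_categories
        weights = np.array([c.weight for c in cats])
        for s in carriers:
            cnv_type = "DUP" if is_dup[s] else "DEL"
            if rng.random() < atypical_prob:
                a, b = np.sort(rng.integers(locus.start, locus.end + 1, size=2))
                start, end = int(a), int(max(b, a + 1))
            else:
                cat = cats[rng.choice(len(cats), p=weights)]
                start, end = cat.start, cat.end
            if rng.random() < locus.qs_noise:
                mag = rng.uniform(0.05, 0.5)
            else:
                mag = rng.uniform(0.5000001, 1.0)
            qs = mag if cnv_type == "DUP" else -mag
            cn = 3 if cnv_type == "DUP" else 1
            rows.append((f"sample_{s}", locus.chrom, start, end, cnv_type, cn, qs))
    calls = pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start", "end", "type", "copy_number", "qs"],
    )
    return calls.sort_values(["chrom", "start", "sample_id"], kind="stable").reset_index(
        drop=True
    )


def _locus_dosages(
    calls: pd.DataFrame, genome: GenomeModel, n_samples: int
) -> dict[str, np.ndarray]:
    """Signed carrier genotype (-1 del, +1 dup, 0 neutral) per locus.

    Uses the generating carrier status regardless of QS: the truth underlying
    the phenotypes is the CNV itself, not its call quality.
    """
    dosages = {locus.locus_id: np.zeros(n_samples, dtype=np.int8) for locus in genome.loci}
    if calls.empty:
        return dosages
    sidx = calls["sample_id"].str.removeprefix("sample_").astype(int).to_numpy()
    for locus in genome.loci:
        g = dosages[locus.locus_id]
        in_locus = (
            (calls["chrom"] == locus.chrom).to_numpy()
            & (calls["start"].to_numpy() >= locus.start)
            & (calls["end"].to_numpy() <= locus.end)
        )
        for row_i in np.flatnonzero(in_locus):
            g[sidx[row_i]] = 1 if calls["type"].iat[row_i] == "DUP" else -1
    return dosages


def _encode_mechanism(g: np.ndarray, mechanism: str) -> np.ndarray:
    """Generative dosage of the signed genotype under a mechanism.

    Used on the causal side only; the analysis-side encodings (with masking)
    live in :mod:`cnvgwas.association`.
    """
    if mechanism == "mirror":
        return g.astype(float)
    if mechanism == "ushape":
        return np.abs(g).astype(float)
    if mechanism == "duponly":
        return (g == 1).astype(float)
    if mechanism == "delonly":
        return (g == -1).astype(float)
    raise ValueError(mechanism)


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept such that mean(expit(alpha + eta)) == target prevalence."""

    def f(alpha):
        return expit(alpha + eta).mean() - target

    return brentq(f, -30.0, 30.0, xtol=1e-10)


def simulate_phenotypes(
    calls: pd.DataFrame,
    genome: GenomeModel,
    effects: Sequence[EffectSpec],
    covariate_spec: CovariateSpec,
    n_samples: int,
    seed: int,
    diseases: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw covariates, disease statuses, onset ages, and BMI.

    ``diseases`` maps disease id -> target prevalence in (0, 1). Disease
    status follows a logistic model whose intercept is calibrated so the
    realized prevalence matches the target; onset ages for cases follow a
    Weibull proportional-hazards model scaled by each effect's hazard ratio;
    controls are administratively censored at the cutoff date. A configured
    fraction of controls is relabeled ``excluded`` to emulate exclusion lists.
    """
    diseases = diseases or {"disease_1": 0.05}
    for d, prev in diseases.items():
        if not (0.0 < prev < 1.0):
            raise ValueError(f"target prevalence for {d} outside (0, 1)")
    locus_ids = {locus.locus_id for locus in genome.loci}
    for eff in effects:
        if eff.locus_id not in locus_ids:
            raise ValueError(f"effect references unknown locus {eff.locus_id}")
        if eff.disease not in diseases:
            raise ValueError(f"effect references unknown disease {eff.disease}")

    rng = child_rng(seed, "phenotypes")
    spec = covariate_spec

    # covariates; birth dates drawn so the baseline age is ~U(40, 70).
    birth_offset = rng.integers(0, 30 * 365, size=n_samples)
    birth = pd.to_datetime(date(1938, 6, 15)) + pd.to_timedelta(birth_offset, unit="D")
    age = np.asarray((pd.to_datetime(BASELINE_DATE) - birth).days, dtype=float) / 365.25
    sex = rng.binomial(1, 0.54, n_samples)  # 1 = female
    array = rng.binomial(1, 0.1, n_samples)
    pcs = rng.standard_normal((n_samples, spec.n_pcs))

    pheno = pd.DataFrame(
        {
            "sample_id": [f"sample_{i}" for i in range(n_samples)],
            "birth_date": birth.strftime("%Y-%m-%d"),
            "age": age,
            "sex": sex,
            "array": array,
        }
    )
    for k in range(spec.n_pcs):
        pheno[f"pc{k + 1}"] = pcs[:, k]

    dosages = _locus_dosages(calls, genome, n_samples)

    # BMI: standardized, shifted by CNV dosage (mediated path).
    bmi = rng.standard_normal(n_samples)
    for eff in effects:
        if eff.bmi_shift != 0.0:
            bmi = bmi + eff.bmi_shift * _encode_mechanism(
                dosages[eff.locus_id], eff.mechanism
            )
    pheno["bmi"] = bmi

    age_c = (age - age.mean()) if n_samples > 1 else age * 0.0
    eta_cov = (
        spec.age_log_odds * age_c
        + spec.sex_log_odds * sex
        + spec.array_log_odds * array
        + spec.pc_log_odds * pcs.sum(axis=1)
        + spec.bmi_log_odds * bmi
    )
    eta_cov = np.asarray(eta_cov, dtype=float)

    censor_age = np.asarray((pd.to_datetime(spec.cutoff) - birth).days, dtype=float) / 365.25

    burden = np.zeros(n_samples, dtype=int)
    for disease, target in diseases.items():
        eta = eta_cov.copy()
        log_hr = np.zeros(n_samples)
        for eff in effects:
            if eff.disease != disease:
                continue
            dose = _encode_mechanism(dosages[eff.locus_id], eff.mechanism)
            eta += eff.log_odds * dose
            log_hr += np.log(eff.hazard_ratio) * dose
        alpha = _calibrate_intercept(eta, target)
        case = rng.random(n_samples) < expit(alpha + eta)

        # Weibull PH onset: S(t) = exp(-(t/scale)^shape * HR).
        e = rng.exponential(1.0, n_samples)
        onset = WEIBULL_SCALE * (e / np.exp(log_hr)) ** (1.0 / WEIBULL_SHAPE)

        status = np.where(case, "case", "control").astype(object)
        controls = np.flatnonzero(~case)
        n_excl = int(round(spec.excluded_fraction * len(controls)))
        if n_excl:
            excl = rng.choice(controls, size=n_excl, replace=False)
            status[excl] = "excluded"

        pheno[f"{disease}_status"] = status
        pheno[f"{disease}_age_at_diagnosis"] = np.where(case, onset, np.nan)
        pheno[f"{disease}_age_last_healthy"] = np.where(
            case, onset, np.asarray(censor_age)
        )
        pheno.loc[pheno[f"{disease}_status"] == "excluded", f"{disease}_age_last_healthy"] = np.nan
        burden += case.astype(int)

    pheno["disease_burden"] = burden
    return pheno


class ReplicationCohort(NamedTuple):
    calls: pd.DataFrame
    phenotypes: pd.DataFrame
    probes: pd.DataFrame


def simulate_replication_cohort(
    genome: GenomeModel,
    effects: Sequence[EffectSpec],
    n_samples: int,
    attenuation: float,
    seed: int,
    covariate_spec: CovariateSpec | None = None,
    diseases: dict[str, float] | None = None,
    probe_keep_fraction: float = 1.0,
) -> ReplicationCohort:
    """Second cohort from the same genome with attenuated effects.

    Effects are multiplied by ``attenuation`` on the log scale (log-odds,
    log-hazard, BMI shift); the probe map may be subsampled to emulate
    platform differences between genotyping arrays.
    """
    if not (0.0 <= attenuation <= 1.0):
        raise ValueError("attenuation must lie in [0, 1]")
    if not (0.0 < probe_keep_fraction <= 1.0):
        raise ValueError("probe_keep_fraction must lie in (0, 1]")
    spec = covariate_spec or CovariateSpec()
    att_effects = [
        replace(
            e,
            log_odds=e.log_odds * attenuation,
            hazard_ratio=e.hazard_ratio**attenuation,
            bmi_shift=e.bmi_shift * attenuation,
        )
        for e in effects
    ]
    rep_seed = child_rng(seed, "replication").integers(0, 2**31 - 1)
    calls = simulate_calls(genome, n_samples, rep_seed)
    pheno = simulate_phenotypes(
        calls, genome, att_effects, spec, n_samples, rep_seed, diseases=diseases
    )
    probes = genome.probe_table()
    if probe_keep_fraction < 1.0:
        rng = child_rng(seed, "replication_probes")
        keep = rng.random(len(probes)) < probe_keep_fraction
        probes = probes.loc[keep].reset_index(drop=True)
    return ReplicationCohort(calls, pheno, probes)


def demo_genome(
    n_loci: int = 3,
    probes_per_locus: int = 12,
    dup_freq: float = 0.004,
    del_freq: float = 0.004,
    background_probes: int = 30,
) -> GenomeModel:
    """Small genome model with evenly spaced probes used by tests and demos."""
    chromosomes: dict[str, int] = {}
    probes: dict[str, np.ndarray] = {}
    loci: list[CnvLocus] = []
    for i in range(n_loci):
        chrom = str(i + 1)
        length = 10_000_000
        chromosomes[chrom] = length
        start, end = 4_000_000, 4_000_000 + 50_000 * (probes_per_locus - 1)
        in_locus = np.linspace(start, end, probes_per_locus).astype(int)
        flank = np.linspace(1_000_000, 3_000_000, background_probes // n_loci + 1).astype(
            int
        )
        probes[chrom] = np.unique(np.concatenate([flank, in_locus]))
        mid = (start + end) // 2
        loci.append(
            CnvLocus(
                locus_id=f"locus_{i + 1}",
                chrom=chrom,
                start=start,
                end=end,
                dup_freq=dup_freq,
                del_freq=del_freq,
                categories=(
                    BreakpointCategory(start, end, 0.7),
                    BreakpointCategory(start, mid, 0.3),
                ),
            )
        )
    return GenomeModel(chromosomes=chromosomes, probes=probes, loci=tuple(loci))
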