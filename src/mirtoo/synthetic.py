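"""Synthetic ddPCR cohort generator.

Emulates the statistical structure of a multi-class FFPE tumor cohort
profiled with an absolute-quantification miRNA panel:

* per-class log-normal abundance profiles — ddPCR copies are positive and
  right-skewed, and class identity lives in log-scale mean shifts on small
  disjoint sets of discriminant miRNAs;
* small within-class sample sizes (a handful of primaries per class);
* liver-site metastases with strongly inflated miR-122-5p, contributed by
  the liver microenvironment rather than the tumor itself;
* patients contributing several spatially distinct metastases of one hidden
  origin;
* overall-survival times whose hazard depends multiplicatively on
  dichotomized (above/below sample median) expression of selected miRNAs,
  with independent exponential censoring.

Every output is a deterministic function of ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .panel import (
    DEFAULT_EXCLUSIONS,
    DEFAULT_PANEL,
    FEMALE_ONLY_CLASSES,
    KNOWN_BIOPSY_SITES,
    MALE_ONLY_CLASSES,
    PREDICTION_CLASSES,
)

#: Hazard ratios for the default survival drivers (high- vs low-expression
#: group): one strongly protective, one strongly adverse, one moderate —
#: the shape of effect a prognostic miRNA screen is expected to detect.
DEFAULT_SURVIVAL_HR_MAP: dict[str, float] = {
    "miR-124-3p": 0.11,
    "miR-375": 9.6,
    "miR-27b-3p": 2.6,
}


class SimulationError(ValueError):
    """Invalid generator configuration or inputs."""


@dataclass(frozen=True)
class ClassProfile:
    """Log-scale expression profile of one tumor class.

    ``mu`` and ``sigma_within`` are per-miRNA log2-scale mean and SD of
    abundance (log2 copies per microlitre); ``prevalence`` is a sampling
    weight used when drawing cohorts of mixed origin.
    """

    class_label: str
    mu: pd.Series
    sigma_within: pd.Series
    prevalence: float = 1.0

    def __post_init__(self) -> None:
        if not self.mu.index.equals(self.sigma_within.index):
            raise SimulationError("mu and sigma_within must cover the same panel")
        if (self.sigma_within.to_numpy() < 0).any():
            raise SimulationError("sigma_within must be non-negative")
        if self.prevalence <= 0:
            raise SimulationError("prevalence must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model (all units log2 unless noted)."""

    n_per_class: int = 5
    class_separation: float = 2.0
    n_discriminant_mirnas_per_class: int = 5
    sigma_within: float = 0.5
    baseline_mu_range: tuple[float, float] = (2.0, 10.0)
    liver_spike_factor: float = 50.0
    survival_hr_map: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SURVIVAL_HR_MAP)
    )
    censoring_rate: float = 0.2
    baseline_hazard: float = 1.0 / 12.0  # per month; median OS on the CUP scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise SimulationError("n_per_class must be >= 2")
        if self.n_discriminant_mirnas_per_class < 1:
            raise SimulationError("need >= 1 discriminant miRNA per class")
        if self.sigma_within < 0:
            raise SimulationError("sigma_within must be >= 0")
        if self.liver_spike_factor < 1:
            raise SimulationError("liver_spike_factor must be >= 1")
        if any(hr <= 0 for hr in self.survival_hr_map.values()):
            raise SimulationError("all hazard ratios must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise SimulationError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise SimulationError("baseline_hazard must be > 0")


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, salt])


def _class_labels(n_classes: int) -> list[str]:
    if n_classes <= len(PREDICTION_CLASSES):
        return list(PREDICTION_CLASSES[:n_classes])
    extra = [f"CLASS{i:02d}" for i in range(n_classes - len(PREDICTION_CLASSES))]
    return list(PREDICTION_CLASSES) + extra


def _draw_sex(label: str, rng: np.random.Generator) -> str:
    if label in MALE_ONLY_CLASSES:
        return "male"
    if label in FEMALE_ONLY_CLASSES:
        return "female"
    return "male" if rng.random() < 0.5 else "female"


def make_class_profiles(
    n_classes: int,
    panel: Sequence[str] = DEFAULT_PANEL,
    config: SimulationConfig | None = None,
    class_labels: Sequence[str] | None = None,
    reserved: Sequence[str] = DEFAULT_EXCLUSIONS,
) -> list[ClassProfile]:
    """Build per-class profiles with disjoint discriminant miRNA sets.

    All classes share a common baseline mean vector (drawn once from
    ``baseline_mu_range``); each class gets an exclusive block of
    ``n_discriminant_mirnas_per_class`` miRNAs whose mean is shifted up by
    ``class_separation`` log2 units. Assays in ``reserved`` (by default the
    two that later leave the prediction panel) are never discriminant, so
    class signal survives the exclusion step intact.
    """
    config = config or SimulationConfig()
    if n_classes < 2:
        raise SimulationError("need at least two classes")
    panel = list(panel)
    eligible = [m for m in panel if m not in set(reserved)]
    need = n_classes * config.n_discriminant_mirnas_per_class
    if need > len(eligible):
        raise SimulationError(
            f"panel too small: {n_classes} classes x "
            f"{config.n_discriminant_mirnas_per_class} discriminant miRNAs "
            f"need {need} eligible assays, have {len(eligible)}"
        )
    labels = list(class_labels) if class_labels is not None else _class_labels(n_classes)
    if len(labels) != n_classes:
        raise SimulationError("class_labels length must equal n_classes")
    rng = _rng(config, salt=1)
    lo, hi = config.baseline_mu_range
    baseline = pd.Series(rng.uniform(lo, hi, size=len(panel)), index=panel)
    order = rng.permutation(len(eligible))
    sigma = pd.Series(config.sigma_within, index=panel, dtype=float)
    profiles = []
    k = config.n_discriminant_mirnas_per_class
    for c, label in enumerate(labels):
        mu = baseline.copy()
        block = [eligible[i] for i in order[c * k : (c + 1) * k]]
        mu[block] += config.class_separation
        profiles.append(
            ClassProfile(
                class_label=label,
                mu=mu,
                sigma_within=sigma.copy(),
                prevalence=1.0 / n_classes,
            )
        )
    return profiles


def _draw_samples(
    profile: ClassProfile, n: int, rng: np.random.Generator
) -> np.ndarray:
    eps = rng.standard_normal((n, len(profile.mu)))
    log2_abund = profile.mu.to_numpy() + eps * profile.sigma_within.to_numpy()
    return np.exp2(log2_abund)


def simulate_reference_cohort(
    profiles: Sequence[ClassProfile],
    config: SimulationConfig | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw the training cohort: ``n_per_class`` primaries per class.

    Abundance of miRNA j in a sample of class k is 2^(mu_kj + eps),
    eps ~ Normal(0, sigma_within_j); strictly positive. Sex is drawn
    consistently with the class (no female TGSC/PRAD, no male OV/UCEC).
    """
    config = config or SimulationConfig()
    rng = _rng(config, salt=2)
    panel = list(profiles[0].mu.index)
    rows, meta_rows = [], []
    for prof in profiles:
        vals = _draw_samples(prof, config.n_per_class, rng)
        for i in range(config.n_per_class):
            sid = f"{prof.class_label}-{i + 1:02d}"
            rows.append(pd.Series(vals[i], index=panel, name=sid))
            meta_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": f"P-{sid}",
                    "sex": _draw_sex(prof.class_label, rng),
                    "role": "reference_primary",
                    "class_label": prof.class_label,
                    "biopsy_site": "primary",
                    "time_months": np.nan,
                    "event": np.nan,
                }
            )
    matrix = ExpressionMatrix(pd.DataFrame(rows))
    return matrix, pd.DataFrame(meta_rows)


def simulate_metastases(
    profiles: Sequence[ClassProfile],
    config: SimulationConfig | None = None,
    assignments: Sequence[tuple[str, str, str]] = (),
    role: str = "cup",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw metastatic samples from their (hidden) origin-class profiles.

    ``assignments`` is a sequence of ``(patient_id, origin_class,
    biopsy_site)`` triples — one per sample, so a repeated patient_id yields
    multiple metastases of that patient, all sharing the origin. Samples
    biopsied from the liver have miR-122-5p multiplied by
    ``liver_spike_factor`` (microenvironment contamination, not tumor
    signal). The origin is recorded in a ``true_class`` column; for
    ``role="known_metastasis"`` it also fills ``class_label``.
    """
    config = config or SimulationConfig()
    if role not in {"cup", "known_metastasis"}:
        raise SimulationError(f"invalid metastasis role {role!r}")
    by_label = {p.class_label: p for p in profiles}
    panel = list(profiles[0].mu.index)
    rng = _rng(config, salt=3)
    patient_sex: dict[str, str] = {}
    patient_origin: dict[str, str] = {}
    rows, meta_rows = [], []
    counter: dict[str, int] = {}
    for patient_id, origin, site in assignments:
        if origin not in by_label:
            raise SimulationError(f"unknown origin class {origin!r}")
        if site not in KNOWN_BIOPSY_SITES:
            raise SimulationError(f"unknown biopsy site {site!r}")
        if patient_origin.setdefault(patient_id, origin) != origin:
            raise SimulationError(
                f"patient {patient_id}: conflicting origin classes"
            )
        prof = by_label[origin]
        if patient_id not in patient_sex:
            patient_sex[patient_id] = _draw_sex(origin, rng)
        vals = _draw_samples(prof, 1, rng)[0]
        if site == "liver" and "miR-122-5p" in prof.mu.index:
            j = panel.index("miR-122-5p")
            vals = vals.copy()
            vals[j] *= config.liver_spike_factor
        counter[patient_id] = counter.get(patient_id, 0) + 1
        sid = f"{patient_id}-M{counter[patient_id]}"
        rows.append(pd.Series(vals, index=panel, name=sid))
        meta_rows.append(
            {
                "sample_id": sid,
                "patient_id": patient_id,
                "sex": patient_sex[patient_id],
                "role": role,
                "class_label": origin if role == "known_metastasis" else np.nan,
                "biopsy_site": site,
                "time_months": np.nan,
                "event": np.nan,
                "true_class": origin,
            }
        )
    matrix = ExpressionMatrix(pd.DataFrame(rows, columns=panel))
    return matrix, pd.DataFrame(meta_rows)


def simulate_survival(
    meta: pd.DataFrame,
    matrix: ExpressionMatrix,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Fill time_months/event per patient from the hazard model.

    Hazard of sample i is ``h0 * prod_m HR_m^g_im`` where ``g_im`` indicates
    expression of driver miRNA m above the sample-median (over the samples
    being simulated). Event times are exponential; censoring is an
    independent exponential race calibrated so that roughly
    ``censoring_rate`` of subjects are censored at baseline hazard.
    """
    config = config or SimulationConfig()
    missing = [m for m in config.survival_hr_map if m not in matrix.data.columns]
    if missing:
        raise SimulationError(
            f"survival_hr_map references miRNAs outside the matrix: {missing}"
        )
    sub = matrix.data.loc[meta["sample_id"]]
    log_hr = np.zeros(len(meta))
    for mirna, hr in config.survival_hr_map.items():
        expr = sub[mirna].to_numpy(dtype=float)
        g = (expr > np.median(expr)).astype(float)
        log_hr += g * np.log(hr)
    hazard = config.baseline_hazard * np.exp(log_hr)
    rng = _rng(config, salt=4)
    t_event = rng.exponential(1.0 / hazard)
    out = meta.copy()
    if config.censoring_rate > 0:
        c_rate = config.baseline_hazard * config.censoring_rate / (
            1 - config.censoring_rate
        )
        t_cens = rng.exponential(1.0 / c_rate, size=len(meta))
    else:
        t_cens = np.full(len(meta), np.inf)
    out["time_months"] = np.minimum(t_event, t_cens)
    out["event"] = (t_event <= t_cens).astype(int)
    return out


def simulate_study(
    config: SimulationConfig | None = None,
    panel: Sequence[str] = DEFAULT_PANEL,
    n_classes: int = 17,
    n_known_metastases: int = 10,
    n_cup_patients: int = 20,
    n_multi_met_patients: int = 5,
    liver_met_frac: float = 0.3,
) -> dict:
    """End-to-end cohort: reference primaries + known metastases + CUPs.

    Returns a dict with keys ``profiles``, ``reference`` (matrix, meta),
    ``known`` (matrix, meta), ``cup`` (matrix, meta with survival filled).
    CUP patients mostly contribute one metastasis; ``n_multi_met_patients``
    of them contribute 2-4 from distinct sites. A ``liver_met_frac`` share
    of metastases is biopsied from the liver (triggering the miR-122-5p
    spike).
    """
    config = config or SimulationConfig()
    profiles = make_class_profiles(n_classes, panel, config)
    reference = simulate_reference_cohort(profiles, config)
    rng = _rng(config, salt=5)
    labels = [p.class_label for p in profiles]

    def pick_site() -> str:
        if rng.random() < liver_met_frac:
            return "liver"
        others = [s for s in KNOWN_BIOPSY_SITES if s != "liver"]
        return others[rng.integers(len(others))]

    known_assign = [
        (f"KM{i + 1:02d}", labels[int(rng.integers(len(labels)))], pick_site())
        for i in range(n_known_metastases)
    ]
    known = simulate_metastases(profiles, config, known_assign, role="known_metastasis")

    cup_assign: list[tuple[str, str, str]] = []
    for i in range(n_cup_patients):
        pid = f"CUP{i + 1:02d}"
        origin = labels[int(rng.integers(len(labels)))]
        n_mets = int(rng.integers(2, 5)) if i < n_multi_met_patients else 1
        for _ in range(n_mets):
            cup_assign.append((pid, origin, pick_site()))
    cup_matrix, cup_meta = simulate_metastases(profiles, config, cup_assign, role="cup")
    cup_meta = simulate_survival(cup_meta, cup_matrix, config)
    return {
        "profiles": profiles,
        "reference": reference,
        "known": (known[0], known[1]),
        "cup": (cup_matrix, cup_meta),
        "config": config,
    }
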