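"""Synthetic BERA biosensor recordings.

The bioelectric recognition assay (BERA) couples live cells on screen-printed
electrodes to a potentiometer.  In a control sample, added acetylcholine causes
a transient membrane depolarization that the cells rapidly cancel out; when
acetylcholinesterase or ion channels are inhibited by pesticide residues, the
stimulation persists and the depolarization is sustained.  This module emulates
that contrast with a rise-and-decay voltage kernel whose decay time constant is
prolonged by dose, a Hill-type dose-response for the depolarization amplitude,
and multiplicative cell-age / cell-generation modifiers.

Each recording is 180 s sampled at 2 Hz: 360 voltage values plus metadata
(pesticide group, MRL dilution, binary label, cell age in days, generation
number).  Sample sets follow the fixed control/positive composition: the
control (label 0) collection mixes blanks with MRL/20 and MRL/10 dilutions in
a 60/20/20 ratio, the positive (label 1) collection mixes MRL/2 and MRL evenly.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

# -- recording contract -------------------------------------------------------

N_POINTS = 360
SAMPLING_RATE_HZ = 2.0
DURATION_S = N_POINTS / SAMPLING_RATE_HZ  # 180 s

#: sample instants in seconds, t_i = i / 2 for i = 0..359
TIME_GRID_S = np.arange(N_POINTS) / SAMPLING_RATE_HZ

GROUPS = ("pyrethroid", "organophosphate", "carbamate")

#: optimal biorecognition cell line per pesticide group
CELL_LINE_BY_GROUP = {
    "pyrethroid": "N2a",          # mouse neuroblastoma (ion-channel target)
    "organophosphate": "SK-N-SH",  # human neuroblastoma (AChE target)
    "carbamate": "Vero",           # monkey kidney, general toxicity response
}


class Dilution(str, enum.Enum):
    """Cumulative-MRL dilution levels of the pesticide mixture."""

    BLANK = "BLANK"
    MRL_20 = "MRL_20"
    MRL_10 = "MRL_10"
    MRL_2 = "MRL_2"
    MRL = "MRL"


#: concentration as a fraction of the cumulative MRL
DILUTION_FRACTION = {
    Dilution.BLANK: 0.0,
    Dilution.MRL_20: 0.05,
    Dilution.MRL_10: 0.1,
    Dilution.MRL_2: 0.5,
    Dilution.MRL: 1.0,
}

CONTROL_DILUTIONS = (Dilution.BLANK, Dilution.MRL_20, Dilution.MRL_10)
POSITIVE_DILUTIONS = (Dilution.MRL_2, Dilution.MRL)

GENERATIONS = (1, 2, 3, 4)


def coerce_dilution(value: "Dilution | str") -> Dilution:
    try:
        return Dilution(value)
    except ValueError:
        raise ValidationError(
            f"unknown dilution level {value!r}; expected one of "
            f"{[d.value for d in Dilution]}"
        ) from None


def label_for(dilution: "Dilution | str") -> int:
    """0 for control-set dilutions (blank, MRL/20, MRL/10), 1 for MRL/2 and MRL."""
    return int(coerce_dilution(dilution) in POSITIVE_DILUTIONS)


# -- domain types -------------------------------------------------------------


@dataclass(frozen=True)
class TimeSeriesRecord:
    """One potentiometric recording with its biological metadata.

    ``values`` holds 360 voltages (Volts) sampled at 2 Hz over 180 s.  The
    binary ``label`` is determined by the dilution: 0 for control-set members,
    1 for positive-set members.  ``cell_line`` is determined by the group.
    """

    values: np.ndarray
    group: str
    dilution: Dilution
    age_days: int
    generation: int
    label: int = dataclasses.field(default=-1)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_POINTS,):
            raise ValidationError(
                f"recording must contain exactly {N_POINTS} values, "
                f"got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("recording contains non-finite voltages")
        object.__setattr__(self, "values", values)
        if self.group not in GROUPS:
            raise ValidationError(f"unknown pesticide group {self.group!r}")
        object.__setattr__(self, "dilution", coerce_dilution(self.dilution))
        expected = label_for(self.dilution)
        if self.label == -1:
            object.__setattr__(self, "label", expected)
        elif self.label != expected:
            raise ValidationError(
                f"label {self.label} inconsistent with dilution "
                f"{self.dilution.value} (expected {expected})"
            )
        if not (isinstance(self.age_days, (int, np.integer)) and self.age_days > 0):
            raise ValidationError("age_days must be a positive integer")
        if self.generation not in GENERATIONS:
            raise ValidationError("generation must be one of {1, 2, 3, 4}")

    @property
    def n_points(self) -> int:
        return N_POINTS

    @property
    def sampling_rate(self) -> float:
        return SAMPLING_RATE_HZ

    @property
    def cell_line(self) -> str:
        return CELL_LINE_BY_GROUP[self.group]


@dataclass
class SimulatorConfig:
    """Constants of the generative signal model.

    Amplitude model: ``amp_max * (amp_floor + amp_dose_weight * h(c))`` scaled
    by the age and generation modifiers, where ``h`` is a Hill function of the
    concentration fraction ``c``.  ``amp_floor`` encodes the acetylcholine-only
    transient that every recording, including blanks, shows.  The decay time
    constant ``decay_tau0`` is prolonged by dose via ``decay_gain``; a longer
    decay is the sustained-depolarization signature of a positive sample.
    """

    baseline_volts: float = 0.10
    drift_slope: float = 0.005      # Volts over the full 180 s trace
    noise_sd: float = 0.005         # Volts, i.i.d. Gaussian per sample
    rise_tau: float = 5.0           # s
    decay_tau0: float = 20.0        # s, zero-dose decay constant
    decay_gain: float = 8.0         # dimensionless dose prolongation factor
    amp_max: float = 0.05           # Volts
    amp_floor: float = 0.3          # dose-free fraction of amp_max
    amp_dose_weight: float = 0.7    # dose-dependent fraction of amp_max
    hill_coef: float = 2.0
    c50_fraction: float = 0.25      # dose (fraction of cumulative MRL) at half effect
    age_coef: float = 0.02          # fractional amplitude change per day of age
    reference_age_days: float = 5.0
    generation_gains: tuple = (1.0, 0.9, 0.8, 0.7)
    mrl_ppm: float = 0.01           # cumulative MRL concentration, ppm
    age_range: tuple = (2, 10)      # inclusive sampling range for age_days
    composition_control: Mapping = field(
        default_factory=lambda: {
            Dilution.BLANK: 0.6,
            Dilution.MRL_20: 0.2,
            Dilution.MRL_10: 0.2,
        }
    )
    composition_positive: Mapping = field(
        default_factory=lambda: {Dilution.MRL_2: 0.5, Dilution.MRL: 0.5}
    )

    def validate(self) -> "SimulatorConfig":
        scalars = {
            "baseline_volts": self.baseline_volts,
            "drift_slope": self.drift_slope,
            "noise_sd": self.noise_sd,
            "rise_tau": self.rise_tau,
            "decay_tau0": self.decay_tau0,
            "decay_gain": self.decay_gain,
            "amp_max": self.amp_max,
            "amp_floor": self.amp_floor,
            "amp_dose_weight": self.amp_dose_weight,
            "hill_coef": self.hill_coef,
            "c50_fraction": self.c50_fraction,
            "age_coef": self.age_coef,
            "reference_age_days": self.reference_age_days,
            "mrl_ppm": self.mrl_ppm,
        }
        for name, value in scalars.items():
            if not np.isfinite(value):
                raise ValidationError(f"config field {name} is not finite")
        for name in ("rise_tau", "decay_tau0"):
            if scalars[name] <= 0:
                raise ValidationError(f"config field {name} must be strictly positive")
        # zero is allowed for noise-free / amplitude-free degenerate traces
        for name in ("noise_sd", "amp_max"):
            if scalars[name] < 0:
                raise ValidationError(f"config field {name} must be non-negative")
        if len(self.generation_gains) != len(GENERATIONS):
            raise ValidationError("generation_gains must have exactly 4 entries")
        if any(g <= 0 or not np.isfinite(g) for g in self.generation_gains):
            raise ValidationError("generation_gains must all be positive and finite")
        for name, comp in (
            ("composition_control", self.composition_control),
            ("composition_positive", self.composition_positive),
        ):
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-12:
                raise ValidationError(f"{name} fractions sum to {total}, not 1")
        lo, hi = self.age_range
        if not (0 < lo <= hi):
            raise ValidationError("age_range must satisfy 0 < low <= high")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generation_gains"] = list(self.generation_gains)
        d["age_range"] = list(self.age_range)
        d["composition_control"] = {
            coerce_dilution(k).value: v for k, v in self.composition_control.items()
        }
        d["composition_positive"] = {
            coerce_dilution(k).value: v for k, v in self.composition_positive.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulatorConfig":
        kwargs = dict(d)
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown simulator config keys: {sorted(unknown)}")
        if "generation_gains" in kwargs:
            kwargs["generation_gains"] = tuple(kwargs["generation_gains"])
        if "age_range" in kwargs:
            kwargs["age_range"] = tuple(kwargs["age_range"])
        for key in ("composition_control", "composition_positive"):
            if key in kwargs:
                kwargs[key] = {
                    coerce_dilution(k): float(v) for k, v in kwargs[key].items()
                }
        return cls(**kwargs).validate()


def covariate_benefit_config(**overrides) -> SimulatorConfig:
    """Conditions under which the age/generation covariates carry real value.

    The dose acts on the depolarization amplitude only (``decay_gain = 0``),
    because amplitude is exactly the channel that cell age and generation
    confound; the covariate spread is widened (generation gains 1.0-0.45,
    5%/day age effect) so that old/late-generation positive samples overlap
    young/early-generation controls in every amplitude-driven statistic.  A
    12-input network then faces irreducible confounding while a 14-input
    network can divide the covariates back out.  Under the default
    configuration the dose-prolonged decay is a covariate-free signature that
    lets both input sets classify near perfectly, leaving no room for a
    measurable covariate benefit.
    """
    cfg = SimulatorConfig(
        decay_gain=0.0,
        generation_gains=(1.0, 0.8, 0.6, 0.45),
        age_coef=0.05,
        **overrides,
    )
    return cfg.validate()


def null_effect_config(**overrides) -> SimulatorConfig:
    """Config with all dose dependence removed (decay and amplitude).

    Every dilution then produces statistically identical traces, so any
    classifier accuracy above chance on such data indicates leakage in the
    pipeline rather than signal.
    """
    cfg = SimulatorConfig(decay_gain=0.0, amp_dose_weight=0.0, **overrides)
    return cfg.validate()


# -- generative model ---------------------------------------------------------


def response_amplitude(
    dilution: "Dilution | str",
    age_days: float,
    generation: int,
    config: SimulatorConfig | None = None,
) -> tuple[float, float]:
    """Depolarization amplitude (V) and decay time constant (s) for one assay.

    The Hill effect ``h(c) = c^n / (c^n + c50^n)`` (with ``h(0) = 0``) drives
    both the amplitude above its acetylcholine-only floor and the prolongation
    of the decay constant; age and generation rescale the amplitude only.
    """
    config = (config or SimulatorConfig()).validate()
    dilution = coerce_dilution(dilution)
    if generation not in GENERATIONS:
        raise ValidationError("generation must be one of {1, 2, 3, 4}")
    if age_days <= 0:
        raise ValidationError("age_days must be positive")

    c = DILUTION_FRACTION[dilution]
    if c == 0.0:
        h = 0.0
    else:
        cn = c ** config.hill_coef
        h = cn / (cn + config.c50_fraction ** config.hill_coef)
    amplitude = (
        config.amp_max
        * (config.amp_floor + config.amp_dose_weight * h)
        * (1.0 + config.age_coef * (age_days - config.reference_age_days))
        * config.generation_gains[generation - 1]
    )
    decay_tau = config.decay_tau0 * (1.0 + config.decay_gain * h)
    return amplitude, decay_tau


def _response_kernel(rise_tau: float, decay_tau: float) -> np.ndarray:
    """Rise-and-decay kernel on the 2 Hz grid, rescaled to unit maximum."""
    k = (1.0 - np.exp(-TIME_GRID_S / rise_tau)) * np.exp(-TIME_GRID_S / decay_tau)
    peak = k.max()
    return k / peak if peak > 0 else k


def generate_sample(
    group: str,
    dilution: "Dilution | str",
    age_days: int,
    generation: int,
    config: SimulatorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> TimeSeriesRecord:
    """Simulate one 360-point potentiometric recording.

    ``values[i] = baseline + drift * t_i/180 + A * k(t_i) + noise`` where the
    amplitude ``A`` and decay constant come from :func:`response_amplitude`
    and ``k`` is the unit-peak rise-and-decay kernel.  Identical seed and
    arguments reproduce the record bit for bit.
    """
    config = (config or SimulatorConfig()).validate()
    rng = rng if rng is not None else np.random.default_rng(0)
    if group not in GROUPS:
        raise ValidationError(f"unknown pesticide group {group!r}")
    amplitude, decay_tau = response_amplitude(dilution, age_days, generation, config)
    values = (
        config.baseline_volts
        + config.drift_slope * (TIME_GRID_S / DURATION_S)
        + amplitude * _response_kernel(config.rise_tau, decay_tau)
    )
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=N_POINTS)
    return TimeSeriesRecord(
        values=values,
        group=group,
        dilution=coerce_dilution(dilution),
        age_days=int(age_days),
        generation=int(generation),
    )


def allocate_counts(n: int, fractions: Mapping) -> dict:
    """Largest-remainder allocation of ``n`` items to the composition fractions.

    Ties in the fractional remainders are broken by the mapping's key order,
    which follows the fixed dilution listing of the sample-set definition.
    """
    if n < 0:
        raise ValidationError("count must be non-negative")
    keys = list(fractions)
    quotas = np.array([n * fractions[k] for k in keys])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    # stable sort: equal remainders keep the listed dilution order
    order = np.argsort(-(quotas - counts), kind="stable")
    for idx in order[:remainder]:
        counts[idx] += 1
    return {k: int(c) for k, c in zip(keys, counts)}


def generate_sample_set(
    group: str,
    n_control: int,
    n_positive: int,
    config: SimulatorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[TimeSeriesRecord]:
    """Simulate a full control + positive sample set for one pesticide group.

    Control records are allocated over blank / MRL-20 / MRL-10 and positive
    records over MRL-2 / MRL by largest-remainder rounding of the composition
    fractions.  Cell age is drawn uniformly from the configured range and the
    generation number uniformly from 1-4.  The returned order is shuffled.

    The random stream is split into named substreams (covariates, noise,
    shuffle) so that enlarging the set does not perturb earlier records.
    """
    config = (config or SimulatorConfig()).validate()
    if n_control < 0 or n_positive < 0:
        raise ValidationError("sample-set counts must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(0)
    cov_rng, noise_rng, shuffle_rng = rng.spawn(3)

    dilution_plan: list[Dilution] = []
    for n, comp in (
        (n_control, config.composition_control),
        (n_positive, config.composition_positive),
    ):
        for dilution, count in allocate_counts(n, comp).items():
            dilution_plan.extend([coerce_dilution(dilution)] * count)

    lo, hi = config.age_range
    records = []
    for dilution in dilution_plan:
        age = int(cov_rng.integers(lo, hi + 1))
        generation = int(cov_rng.integers(1, 5))
        records.append(
            generate_sample(group, dilution, age, generation, config, noise_rng)
        )
    perm = shuffle_rng.permutation(len(records))
    return [records[i] for i in perm]


#: per-group (n_control, n_positive) sizes of the full-scale datasets
PAPER_SCALE_SIZES = {
    "pyrethroid": (405, 404),
    "organophosphate": (506, 700),
    "carbamate": (585, 585),
}


def generate_paper_scale_datasets(
    config: SimulatorConfig | None = None,
    rng: "np.random.Generator | int | None" = None,
) -> dict[str, list[TimeSeriesRecord]]:
    """One full-scale dataset per pesticide group.

    Pyrethroid: 405 control + 404 positive; organophosphate: 506 + 700;
    carbamate: 585 + 585.  Each group gets its own substream of ``rng``.
    """
    config = (config or SimulatorConfig()).validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    datasets = {}
    for group, group_rng in zip(GROUPS, rng.spawn(len(GROUPS))):
        n_control, n_positive = PAPER_SCALE_SIZES[group]
        datasets[group] = generate_sample_set(
            group, n_control, n_positive, config, group_rng
        )
    return datasets


# -- dataset CSV dialect ------------------------------------------------------

_VALUE_COLUMNS = [f"v{i:03d}" for i in range(N_POINTS)]
_META_COLUMNS = ["group", "cell_line", "dilution", "label", "age_days", "generation"]


def records_to_dataframe(records: Iterable[TimeSeriesRecord]) -> pd.DataFrame:
    records = list(records)
    meta = pd.DataFrame(
        {
            "group": [r.group for r in records],
            "cell_line": [r.cell_line for r in records],
            "dilution": [r.dilution.value for r in records],
            "label": [r.label for r in records],
            "age_days": [r.age_days for r in records],
            "generation": [r.generation for r in records],
        }
    )
    values = pd.DataFrame(
        np.vstack([r.values for r in records]) if records else
        np.empty((0, N_POINTS)),
        columns=_VALUE_COLUMNS,
    )
    return pd.concat([meta, values], axis=1)


def dataframe_to_records(frame: pd.DataFrame) -> list[TimeSeriesRecord]:
    missing = [c for c in _META_COLUMNS + _VALUE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"dataset is missing {len(missing)} required columns, "
            f"first few: {missing[:4]}"
        )
    records = []
    values = frame[_VALUE_COLUMNS].to_numpy(dtype=float)
    for pos, (_, row) in enumerate(frame.iterrows()):
        try:
            records.append(
                TimeSeriesRecord(
                    values=values[pos],
                    group=row["group"],
                    dilution=row["dilution"],
                    age_days=int(row["age_days"]),
                    generation=int(row["generation"]),
                    label=int(row["label"]),
                )
            )
        except (ValidationError, TypeError, ValueError) as exc:
            raise ValidationError(f"dataset row {pos}: {exc}") from exc
    return records


def write_dataset_csv(records: Iterable[TimeSeriesRecord], path) -> None:
    """UTF-8 CSV, one row per record: metadata columns then v000..v359."""
    records_to_dataframe(records).to_csv(path, index=False, float_format="%.17g")


def read_dataset_csv(path) -> list[TimeSeriesRecord]:
    # round_trip parsing keeps the written voltages bit-identical
    return dataframe_to_records(pd.read_csv(path, float_precision="round_trip"))
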