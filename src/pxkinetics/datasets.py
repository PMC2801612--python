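"""Data model and I/O for labeling-ratio observations.

One experimental group (genotype x tissue) contributes ten independent
labeling observations: four single-pulse BrdU measurements (days 0, 1, 2
and 14, each from a 1-day labeling window ending at the measure day) and
three dual-analog pulse/chase protocols (named
"pulse1-pulse2-measureday": 2-2-4, 2-2-14 and 7-7-14) read out for CldU
and IdU separately.

CldU/IdU ratios measured from drinking-water administration under-detect
proliferation relative to injected BrdU; published tables store them
already rescaled by the conventional factor of 3, flagged here with
``scale_applied``.  The inference module folds the detection-scale
parameter eta into the comparison.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "GENOTYPES",
    "TISSUES",
    "GROUPS",
    "LabelingProtocol",
    "LabelingObservation",
    "StudyDataset",
    "brdu_protocol",
    "dual_protocol",
    "standard_design",
    "builtin_table1",
    "builtin_model_predictions",
    "read_dataset",
    "write_dataset",
]

GENOTYPES = ("WT", "R24C")
TISSUES = ("beta", "duct")
#: The four genotype x tissue groups, in "GENOTYPE:tissue" notation.
GROUPS = tuple(f"{g}:{t}" for g in GENOTYPES for t in TISSUES)

_DUAL_PROTOCOLS = {
    "2-2-4": ((0.0, 2.0), (2.0, 4.0), 4.0),
    "2-2-14": ((0.0, 2.0), (2.0, 4.0), 14.0),
    "7-7-14": ((0.0, 7.0), (7.0, 14.0), 14.0),
}
_BRDU_DAYS = (0.0, 1.0, 2.0, 14.0)


@dataclass(frozen=True)
class LabelingProtocol:
    """A pulse(/pulse)/chase schedule with a measurement day."""

    name: str
    pulse1: tuple[float, float]
    measure_day: float
    pulse2: tuple[float, float] | None = None
    analog1: str = "BrdU"
    analog2: str | None = None

    def __post_init__(self) -> None:
        if self.pulse1[0] > self.pulse1[1]:
            raise ValueError(f"{self.name}: pulse1 window inverted")
        if self.pulse2 is not None:
            if self.pulse2[0] > self.pulse2[1]:
                raise ValueError(f"{self.name}: pulse2 window inverted")
            if self.pulse1[1] > self.pulse2[0]:
                raise ValueError(f"{self.name}: pulse windows overlap")
            if self.pulse2[1] > self.measure_day:
                raise ValueError(f"{self.name}: pulse2 ends after the measure day")
        elif self.pulse1[1] > self.measure_day:
            raise ValueError(f"{self.name}: pulse1 ends after the measure day")

    def window(self, analog: str) -> tuple[float, float]:
        """Labeling window for one analog of this protocol."""
        if analog == self.analog1:
            return self.pulse1
        if self.analog2 is not None and analog == self.analog2:
            assert self.pulse2 is not None
            return self.pulse2
        raise KeyError(f"analog {analog!r} not part of protocol {self.name}")


def brdu_protocol(measure_day: float) -> LabelingProtocol:
    """Single-analog BrdU protocol: a 1-day window ending at ``measure_day``."""
    day = int(measure_day) if float(measure_day).is_integer() else measure_day
    return LabelingProtocol(
        name=f"day{day}",
        pulse1=(measure_day - 1.0, measure_day),
        measure_day=measure_day,
        analog1="BrdU",
    )


def dual_protocol(name: str) -> LabelingProtocol:
    """One of the named CldU/IdU pulse-pulse-chase protocols."""
    try:
        pulse1, pulse2, measure = _DUAL_PROTOCOLS[name]
    except KeyError:
        raise KeyError(f"unknown dual-analog protocol {name!r}; "
                       f"known: {sorted(_DUAL_PROTOCOLS)}") from None
    return LabelingProtocol(
        name=name, pulse1=pulse1, pulse2=pulse2, measure_day=measure,
        analog1="CldU", analog2="IdU",
    )


def protocol_by_name(name: str) -> LabelingProtocol:
    if name in _DUAL_PROTOCOLS:
        return dual_protocol(name)
    if name.startswith("day"):
        return brdu_protocol(float(name[3:]))
    raise KeyError(f"unknown protocol {name!r}")


def standard_design() -> list[tuple[LabelingProtocol, str]]:
    """The ten (protocol, analog) cells of the full labeling design."""
    design: list[tuple[LabelingProtocol, str]] = [
        (brdu_protocol(d), "BrdU") for d in _BRDU_DAYS
    ]
    design += [(dual_protocol(n), "CldU") for n in _DUAL_PROTOCOLS]
    design += [(dual_protocol(n), "IdU") for n in _DUAL_PROTOCOLS]
    return design


@dataclass(frozen=True)
class LabelingObservation:
    """One measured labeling ratio (percent) with its replicate scatter."""

    group: tuple[str, str]
    protocol: LabelingProtocol
    analog: str
    mean_ratio: float
    sd_ratio: float
    n_replicates: int
    scale_applied: bool = False

    def __post_init__(self) -> None:
        if self.mean_ratio < 0:
            raise ValueError("mean_ratio must be >= 0")
        if self.sd_ratio < 0:
            raise ValueError("sd_ratio must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.protocol.window(self.analog)  # analog must belong to the protocol

    @property
    def key(self) -> tuple[str, str]:
        return (self.protocol.name, self.analog)


@dataclass(frozen=True)
class StudyDataset:
    """The ordered collection of labeling observations for one group."""

    observations: tuple[LabelingObservation, ...]

    def __post_init__(self) -> None:
        keys = [o.key for o in self.observations]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise ValueError(f"duplicate (protocol, analog) observations: {sorted(dupes)}")
        groups = {o.group for o in self.observations}
        if len(groups) > 1:
            raise ValueError(f"observations span multiple groups: {sorted(groups)}")

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    @property
    def group(self) -> tuple[str, str]:
        return self.observations[0].group

    def observation(self, protocol_name: str, analog: str) -> LabelingObservation:
        for o in self.observations:
            if o.key == (protocol_name, analog):
                return o
        raise KeyError((protocol_name, analog))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": f"{o.group[0]}:{o.group[1]}",
                "protocol": o.protocol.name,
                "analog": o.analog,
                "mean": o.mean_ratio,
                "sd": o.sd_ratio,
                "n": o.n_replicates,
                "scale_applied": o.scale_applied,
            }
            for o in self.observations
        ]
        return pd.DataFrame(rows)


def _parse_group(group) -> tuple[str, str]:
    if isinstance(group, str):
        try:
            genotype, tissue = group.split(":")
        except ValueError:
            raise ValueError(
                f"group {group!r} not in 'GENOTYPE:tissue' form (e.g. 'WT:beta')"
            ) from None
    else:
        genotype, tissue = group
    if tissue == "islet_beta":
        tissue = "beta"
    if genotype not in GENOTYPES or tissue not in TISSUES:
        raise KeyError(
            f"unknown group {genotype}:{tissue}; expected genotype in {GENOTYPES} "
            f"and tissue in {TISSUES}"
        )
    return genotype, tissue


def _table1_frame() -> pd.DataFrame:
    with importlib.resources.files("pxkinetics.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def _ordered_rows(df: pd.DataFrame) -> pd.DataFrame:
    order = {(p.name, a): i for i, (p, a) in enumerate(standard_design())}
    df = df.copy()
    df["_ord"] = [
        order.get((r.protocol, r.analog), len(order)) for r in df.itertuples()
    ]
    return df.sort_values("_ord").drop(columns="_ord")


def builtin_table1(group) -> StudyDataset:
    """The published labeling-ratio table for one group, as measured.

    Means and SDs are in percent; CldU/IdU rows carry the conventional
    3-fold detection rescaling (``scale_applied=True``).  Replicate counts
    were published only as a 2-4 range, so a neutral n=3 is stored.
    """
    genotype, tissue = _parse_group(group)
    df = _table1_frame()
    df = _ordered_rows(df[(df.genotype == genotype) & (df.tissue == tissue)])
    obs = tuple(
        LabelingObservation(
            group=(genotype, tissue),
            protocol=protocol_by_name(r.protocol),
            analog=r.analog,
            mean_ratio=float(r.mean),
            sd_ratio=float(r.sd),
            n_replicates=int(r.n),
            scale_applied=bool(r.scale_applied),
        )
        for r in df.itertuples()
    )
    return StudyDataset(obs)


def builtin_model_predictions(group) -> dict[tuple[str, str], float]:
    """The published best-fit model column for one group (percent).

    Keyed by (protocol name, analog); useful as a reference when
    validating refits.
    """
    genotype, tissue = _parse_group(group)
    df = _table1_frame()
    df = _ordered_rows(df[(df.genotype == genotype) & (df.tissue == tissue)])
    return {(r.protocol, r.analog): float(r.model_prediction) for r in df.itertuples()}


_REQUIRED_COLUMNS = ("group", "protocol", "analog", "mean", "sd", "n", "scale_applied")


def read_dataset(path, require_complete: bool = True) -> StudyDataset:
    """Read a labeling dataset from a delimited table.

    The file must be comma-separated with a header row containing the
    columns ``group, protocol, analog, mean, sd, n, scale_applied``.
    With ``require_complete`` (default) the ten cells of the standard
    design must all be present.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    observations = []
    for i, r in enumerate(df.itertuples()):
        where = f"{path} row {i + 1} ({r.protocol}, {r.analog})"
        if pd.isna(r.sd):
            raise ValueError(
                f"{where}: blank sd; supply a replicate SD or an explicit "
                "uncertainty (rows with n=1 need a stated policy)"
            )
        if float(r.sd) < 0:
            raise ValueError(f"{where}: negative sd {r.sd}")
        try:
            observations.append(
                LabelingObservation(
                    group=_parse_group(r.group),
                    protocol=protocol_by_name(str(r.protocol)),
                    analog=str(r.analog),
                    mean_ratio=float(r.mean),
                    sd_ratio=float(r.sd),
                    n_replicates=int(r.n),
                    scale_applied=bool(r.scale_applied),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{where}: {exc}") from exc
    try:
        dataset = StudyDataset(tuple(observations))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    if require_complete:
        have = {o.key for o in dataset}
        expected = {(p.name, a) for p, a in standard_design()}
        absent = expected - have
        if absent:
            raise ValueError(
                f"{path}: dataset incomplete; missing (protocol, analog) cells "
                f"{sorted(absent)}"
            )
    return dataset


def write_dataset(dataset: StudyDataset, path) -> None:
    """Write a dataset as CSV; ``read_dataset`` round-trips it exactly."""
    dataset.to_frame().to_csv(Path(path), index=False)
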