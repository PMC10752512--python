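"""Canonical tabular schemas shared by synthetic and user-supplied inputs.

Every run of the model consumes five tables:

* a census population by single year of age (``population.csv``),
* platform-use prevalence by survey age group with 95%-CI margins
  (``prevalence.csv``),
* minutes/day among users by age band (``minutes.csv``),
* externally reported platform user totals by age band, the calibration
  targets (``user_totals.csv``),
* total annual advertising revenue per platform (``revenue.csv``).

All files are UTF-8 CSV with a header row and period decimal separator.
Open-ended top bands ("65 and older") are written with ``group_hi`` equal
to the literal ``+`` and are resolved to the configured maximum age on
load. Loaders validate every invariant and raise :class:`ValidationError`
with the offending file, row and column; they never coerce silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "AgeBand",
    "AgeGroupEstimate",
    "UserTotal",
    "PopulationTable",
    "PlatformInputs",
    "RunConfig",
    "load_population",
    "load_platform_inputs",
    "load_run_config",
    "write_population",
    "write_band_table",
    "write_user_totals",
    "write_revenue",
    "write_inputs_config",
    "write_outputs",
    "file_digest",
]


class ValidationError(ValueError):
    """An input table or configuration violates its documented schema."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class AgeBand:
    """Inclusive age band ``[lo, hi]``; ``open_ended`` marks a top band
    such as "65+" whose ``hi`` has been resolved to the model's maximum age."""

    lo: int
    hi: int
    open_ended: bool = False

    def __post_init__(self) -> None:
        _require(self.lo <= self.hi, f"age band {self.lo}-{self.hi}: lo > hi")
        _require(self.lo >= 0, f"age band {self.lo}-{self.hi}: negative age")

    @property
    def label(self) -> str:
        return f"{self.lo}+" if self.open_ended else f"{self.lo}-{self.hi}"

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2.0

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    def overlaps(self, other: "AgeBand") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi


@dataclass(frozen=True)
class AgeGroupEstimate:
    """A survey age band with a point estimate and the ± half-width of its
    95% confidence interval (``margin95``), in the same units as the
    estimate (proportion in [0,1] or minutes/day)."""

    band: AgeBand
    estimate: float
    margin95: float
    source_label: str = ""

    def __post_init__(self) -> None:
        _require(self.margin95 >= 0, f"band {self.band.label}: margin95 < 0")
        _require(self.estimate >= 0, f"band {self.band.label}: negative estimate")

    @property
    def group_lo(self) -> int:
        return self.band.lo

    @property
    def group_hi(self) -> int:
        return self.band.hi


@dataclass(frozen=True)
class UserTotal:
    """Externally reported number of platform users in an age band; the
    calibration target the modeled age curve must reproduce in aggregate."""

    band: AgeBand
    users: float

    def __post_init__(self) -> None:
        _require(self.users >= 0, f"band {self.band.label}: negative user total")


@dataclass(frozen=True)
class PopulationTable:
    """Population counts by single year of age, contiguous from 0 to
    ``age_max``. Persons older than ``age_max`` are accumulated into the
    top age before loading."""

    ages: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "counts", counts)
        _require(ages.ndim == 1 and counts.shape == ages.shape,
                 "population: ages and counts must be 1-D and equal length")
        _require(ages.size > 0, "population: empty table")
        _require(np.array_equal(ages, np.arange(ages[0], ages[0] + ages.size)),
                 "population: ages must be unique and contiguous")
        _require(ages[0] == 0, "population: ages must start at 0")
        _require(bool(np.all(counts >= 0)), "population: negative count")

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def band_total(self, band: AgeBand) -> float:
        _require(band.hi <= self.age_max,
                 f"band {band.label} outside population range 0-{self.age_max}")
        return float(self.counts[band.lo:band.hi + 1].sum())


def _check_no_overlap(bands: Sequence[AgeBand], what: str, platform: str) -> None:
    ordered = sorted(bands, key=lambda b: b.lo)
    for a, b in zip(ordered, ordered[1:]):
        _require(not a.overlaps(b),
                 f"{platform}: {what} bands {a.label} and {b.label} overlap")


@dataclass(frozen=True)
class PlatformInputs:
    """All group-level inputs for one platform: use prevalence by survey
    band, minutes/day among users by band, reported user totals per band
    (calibration targets) and total annual ad revenue in USD."""

    platform_id: str
    use_prevalence: tuple[AgeGroupEstimate, ...]
    minutes: tuple[AgeGroupEstimate, ...]
    group_user_totals: tuple[UserTotal, ...]
    total_revenue: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "use_prevalence", tuple(self.use_prevalence))
        object.__setattr__(self, "minutes", tuple(self.minutes))
        object.__setattr__(self, "group_user_totals", tuple(self.group_user_totals))
        pid = self.platform_id
        _require(self.total_revenue > 0, f"{pid}: total_revenue must be > 0")
        _require(len(self.use_prevalence) >= 2,
                 f"{pid}: need at least 2 prevalence bands")
        _require(len(self.minutes) >= 1, f"{pid}: need at least 1 minutes band")
        for est in self.use_prevalence:
            _require(0.0 <= est.estimate <= 1.0,
                     f"{pid}: prevalence {est.estimate} for band "
                     f"{est.band.label} outside [0, 1]")
        _check_no_overlap([e.band for e in self.use_prevalence], "prevalence", pid)
        _check_no_overlap([e.band for e in self.minutes], "minutes", pid)
        _check_no_overlap([t.band for t in self.group_user_totals], "user-total", pid)


def _default_youth_bands() -> tuple[AgeBand, ...]:
    return (AgeBand(0, 12), AgeBand(13, 17), AgeBand(0, 17))


@dataclass(frozen=True)
class RunConfig:
    """Run-level settings.

    ``n_candidates`` parameter sets are drawn per platform and the
    ``n_keep`` best-fitting retained as the uncertainty ensemble;
    ``ui_lo``/``ui_hi`` are the percentiles of that ensemble reported as
    the uncertainty interval. ``child_minutes_fallback`` is the minutes/day
    assumed for ages below 18 when a platform's minutes table has no band
    covering them (the convention used when a platform is too small to
    appear in children's screen-time rankings).
    """

    seed: int = 0
    age_max: int = 84
    n_candidates: int = 10_000
    n_keep: int = 100
    ui_lo: float = 2.5
    ui_hi: float = 97.5
    youth_bands: tuple[AgeBand, ...] = field(default_factory=_default_youth_bands)
    child_minutes_fallback: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "youth_bands", tuple(self.youth_bands))
        _require(self.n_keep >= 1, "n_keep must be >= 1")
        _require(self.n_keep <= self.n_candidates, "n_keep > n_candidates")
        _require(0 <= self.ui_lo < self.ui_hi <= 100,
                 "percentiles must satisfy 0 <= ui_lo < ui_hi <= 100")
        _require(self.age_max >= 1, "age_max must be >= 1")
        _require(self.seed >= 0, "seed must be non-negative")
        for b in self.youth_bands:
            _require(b.hi <= self.age_max,
                     f"reporting band {b.label} exceeds age_max {self.age_max}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["youth_bands"] = [b.label for b in self.youth_bands]
        return d


# ---------------------------------------------------------------------------
# loaders


def _read_csv(path: Path | str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    _require(path.exists(), f"{path}: file not found")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    _require(not missing, f"{path}: missing column(s) {missing}")
    return df


def _as_number(raw: str, path: Path | str, row: int, col: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ValidationError(
            f"{path}, row {row}, column '{col}': not a number: {raw!r}") from None


def _as_int(raw: str, path: Path | str, row: int, col: str) -> int:
    value = _as_number(raw, path, row, col)
    if value != int(value):
        raise ValidationError(
            f"{path}, row {row}, column '{col}': not an integer: {raw!r}")
    return int(value)


def load_population(path: Path | str, age_max: int | None = None) -> PopulationTable:
    """Read a census table (columns ``age,count``) into a validated
    :class:`PopulationTable`. If ``age_max`` is given, counts for older
    ages are accumulated into ``age_max`` (the top age is open-ended)."""
    df = _read_csv(path, ["age", "count"])
    ages, counts = [], []
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        age = _as_int(rec.age, path, row, "age")
        count = _as_number(rec.count, path, row, "count")
        if count < 0:
            raise ValidationError(
                f"{path}, row {row}, column 'count': negative count {count}")
        ages.append(age)
        counts.append(count)
    order = np.argsort(ages, kind="stable")
    ages_arr = np.asarray(ages)[order]
    counts_arr = np.asarray(counts, dtype=float)[order]
    if np.unique(ages_arr).size != ages_arr.size:
        dup = int(ages_arr[np.diff(ages_arr, prepend=-1) == 0][0])
        raise ValidationError(f"{path}: duplicate age {dup} in column 'age'")
    if age_max is not None and ages_arr[-1] > age_max:
        keep = ages_arr <= age_max
        spill = counts_arr[~keep].sum()
        ages_arr, counts_arr = ages_arr[keep], counts_arr[keep]
        counts_arr[-1] += spill
    return PopulationTable(ages=ages_arr, counts=counts_arr)


def _parse_band(lo_raw: str, hi_raw: str, age_max: int,
                path: Path | str, row: int) -> AgeBand:
    lo = _as_int(lo_raw, path, row, "group_lo")
    hi_txt = str(hi_raw).strip()
    if hi_txt in {"+", ""}:
        return AgeBand(lo, age_max, open_ended=True)
    return AgeBand(lo, _as_int(hi_txt, path, row, "group_hi"))


def _load_band_table(path: Path | str, age_max: int,
                     proportion: bool) -> dict[str, list[AgeGroupEstimate]]:
    df = _read_csv(path, ["platform", "group_lo", "group_hi", "estimate", "margin95"])
    out: dict[str, list[AgeGroupEstimate]] = {}
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        band = _parse_band(rec.group_lo, rec.group_hi, age_max, path, row)
        est = _as_number(rec.estimate, path, row, "estimate")
        margin = _as_number(rec.margin95, path, row, "margin95")
        if proportion and not 0.0 <= est <= 1.0:
            raise ValidationError(
                f"{path}, row {row}, column 'estimate': proportion {est} "
                f"outside [0, 1]")
        if margin < 0:
            raise ValidationError(
                f"{path}, row {row}, column 'margin95': negative margin {margin}")
        source = getattr(rec, "source", "")
        out.setdefault(str(rec.platform), []).append(
            AgeGroupEstimate(band, est, margin, str(source)))
    return out


def _load_user_totals(path: Path | str, age_max: int) -> dict[str, list[UserTotal]]:
    df = _read_csv(path, ["platform", "group_lo", "group_hi", "users"])
    out: dict[str, list[UserTotal]] = {}
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        band = _parse_band(rec.group_lo, rec.group_hi, age_max, path, row)
        users = _as_number(rec.users, path, row, "users")
        out.setdefault(str(rec.platform), []).append(UserTotal(band, users))
    return out


def _load_revenue(path: Path | str) -> dict[str, float]:
    df = _read_csv(path, ["platform", "total_revenue_usd"])
    out: dict[str, float] = {}
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        pid = str(rec.platform)
        _require(pid not in out, f"{path}, row {row}: duplicate platform {pid!r}")
        out[pid] = _as_number(rec.total_revenue_usd, path, row, "total_revenue_usd")
    return out


def load_platform_inputs(config_path: Path | str,
                         age_max: int | None = None) -> list[PlatformInputs]:
    """Assemble one :class:`PlatformInputs` per platform from the CSV files
    referenced by a YAML run configuration (see :func:`write_inputs_config`
    for the layout). Platforms are returned in the order they appear in
    the revenue table."""
    config_path = Path(config_path)
    _require(config_path.exists(), f"{config_path}: file not found")
    cfg = yaml.safe_load(config_path.read_text()) or {}
    files = cfg.get("inputs", cfg)
    if age_max is None:
        age_max = int(cfg.get("run", {}).get("age_max", 84))
    base = config_path.parent

    def _resolve(key: str) -> Path:
        _require(key in files, f"{config_path}: missing 'inputs.{key}'")
        return base / files[key]

    prevalence = _load_band_table(_resolve("prevalence"), age_max, proportion=True)
    minutes = _load_band_table(_resolve("minutes"), age_max, proportion=False)
    totals = _load_user_totals(_resolve("user_totals"), age_max)
    revenue = _load_revenue(_resolve("revenue"))

    platforms: list[PlatformInputs] = []
    for pid in revenue:
        _require(pid in prevalence, f"{pid}: no prevalence bands provided")
        _require(pid in minutes, f"{pid}: no minutes bands provided")
        _require(pid in totals, f"{pid}: no user-total calibration targets")
        for t in totals[pid]:
            _require(t.band.hi <= age_max,
                     f"{pid}: calibration band {t.band.label} exceeds "
                     f"age_max {age_max}")
        platforms.append(PlatformInputs(
            platform_id=pid,
            use_prevalence=tuple(prevalence[pid]),
            minutes=tuple(minutes[pid]),
            group_user_totals=tuple(totals[pid]),
            total_revenue=revenue[pid],
        ))
    missing_revenue = set(prevalence) - set(revenue)
    _require(not missing_revenue,
             f"missing total_revenue for platform(s) {sorted(missing_revenue)}")
    return platforms


def load_run_config(config_path: Path | str) -> RunConfig:
    """Read the ``run:`` section of a YAML run configuration."""
    cfg = yaml.safe_load(Path(config_path).read_text()) or {}
    run = dict(cfg.get("run", {}))
    if "youth_bands" in run:
        run["youth_bands"] = tuple(
            AgeBand(int(b[0]), int(b[1])) for b in run["youth_bands"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(run) - known
    _require(not unknown, f"{config_path}: unknown run setting(s) {sorted(unknown)}")
    return RunConfig(**run)


# ---------------------------------------------------------------------------
# writers


def _band_cells(band: AgeBand) -> tuple[int, str]:
    return band.lo, ("+" if band.open_ended else str(band.hi))


def write_population(pop: PopulationTable, path: Path | str) -> Path:
    path = Path(path)
    pd.DataFrame({"age": pop.ages, "count": pop.counts}).to_csv(path, index=False)
    return path


def write_band_table(tables: Mapping[str, Sequence[AgeGroupEstimate]],
                     path: Path | str) -> Path:
    rows = []
    for pid, ests in tables.items():
        for e in ests:
            lo, hi = _band_cells(e.band)
            rows.append((pid, lo, hi, e.estimate, e.margin95, e.source_label))
    path = Path(path)
    pd.DataFrame(rows, columns=["platform", "group_lo", "group_hi",
                                "estimate", "margin95", "source"]
                 ).to_csv(path, index=False)
    return path


def write_user_totals(tables: Mapping[str, Sequence[UserTotal]],
                      path: Path | str) -> Path:
    rows = []
    for pid, totals in tables.items():
        for t in totals:
            lo, hi = _band_cells(t.band)
            rows.append((pid, lo, hi, t.users))
    path = Path(path)
    pd.DataFrame(rows, columns=["platform", "group_lo", "group_hi", "users"]
                 ).to_csv(path, index=False)
    return path


def write_revenue(revenue: Mapping[str, float], path: Path | str) -> Path:
    path = Path(path)
    pd.DataFrame(list(revenue.items()),
                 columns=["platform", "total_revenue_usd"]).to_csv(path, index=False)
    return path


def write_inputs_config(path: Path | str, *, run: Mapping | None = None,
                        **file_keys: str) -> Path:
    """Write the YAML configuration tying the five input CSVs together."""
    path = Path(path)
    doc: dict = {"inputs": dict(file_keys)}
    if run:
        doc["run"] = dict(run)
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def file_digest(path: Path | str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


_OUTPUT_FILES = {
    "users": "users_by_band.csv",
    "revenue": "revenue_by_band.csv",
    "share": "revenue_share_by_band.csv",
}


def write_outputs(summaries: Mapping[str, pd.DataFrame], out_dir: Path | str,
                  config: RunConfig,
                  input_digests: Mapping[str, str] | None = None) -> list[Path]:
    """Write the three summary CSVs (users, revenue, revenue share by
    reporting band, each with ensemble mean and UI bounds) plus a JSON
    manifest recording the configuration, seed and input digests. Output
    is byte-identical for identical inputs: the manifest carries no
    timestamps and keys are sorted."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for key, fname in _OUTPUT_FILES.items():
            df = summaries.get(key)
            if df is None:
                df = pd.DataFrame(columns=["platform", "band", "mean",
                                           "ui_lo", "ui_hi"])
            p = out_dir / fname
            df.to_csv(p, index=False)
            written.append(p)
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "input_digests": dict(input_digests or {}),
            "percentile_definition": ("linear interpolation between closest "
                                      "order statistics (type 7)"),
            "outputs": sorted(f.name for f in written),
        }
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(mpath)
        return written
    except OSError as exc:
        raise OSError(f"cannot write outputs under {out_dir}: {exc}") from exc
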