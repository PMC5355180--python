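"""Domain types and scoring arithmetic for sea-urchin fertilization trials.

A fertilization trial exposes the eggs of one female to a serial dilution of
one male's sperm under a fixed seawater treatment.  Each 25-ml vial is scored
under the microscope into four categories:

* ``n_unfert``   -- no fertilization membrane,
* ``n_tight``    -- tight (abnormal) fertilization membrane,
* ``n_abn_dev``  -- normal envelope but unequal cleavage,
* ``n_normal``   -- smooth raised envelope, equal cleavage (derived).

From these, three proportions are computed per vial:

* total fertilization       ``TF  = (scored - unfert) / scored``
* abnormal fertilization    ``AbnF = (tight + abn_dev) / (scored - unfert)``
* normal fertilization      ``NF  = TF * (1 - AbnF)``

``AbnF`` is undefined when nothing fertilized (``TF == 0``); this is carried
as an explicit flag rather than a 0 or an error, because such vials never
enter abnormal-fertilization model fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SITES = ("FC", "BMR", "SB")
TREATMENT_LABELS = ("8.03", "7.87", "7.76", "7.61")

#: Open analysis windows (sperm/ul) outside which the response is uniformly
#: 0 or 100% and would induce underdispersion in model fits.
ANALYSIS_WINDOWS = {
    "TF": (1.0, 2e5),
    "AbnF": (1e2, 2e7),
}

TRIAL_CSV_COLUMNS = [
    "site",
    "pair_id",
    "ph_treatment",
    "ph_measured",
    "vial_index",
    "sperm_conc",
    "n_scored",
    "n_unfert",
    "n_tight",
    "n_abn_dev",
]


class TrialValidationError(ValueError):
    """Raised when counts or trial records violate a structural invariant."""


@dataclass(frozen=True)
class VialCounts:
    """Scored embryo counts for one vial.

    ``n_normal`` is derived: counts must satisfy
    ``n_unfert + n_tight + n_abn_dev + n_normal == n_scored``.
    """

    n_scored: int
    n_unfert: int
    n_tight: int
    n_abn_dev: int

    def __post_init__(self) -> None:
        for name in ("n_scored", "n_unfert", "n_tight", "n_abn_dev"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TrialValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise TrialValidationError(f"{name} must be >= 0, got {v}")
        if self.n_unfert > self.n_scored:
            raise TrialValidationError(
                f"n_unfert ({self.n_unfert}) exceeds n_scored ({self.n_scored})"
            )
        if self.n_tight + self.n_abn_dev > self.n_scored - self.n_unfert:
            raise TrialValidationError(
                "n_tight + n_abn_dev exceeds the fertilized count "
                f"({self.n_tight} + {self.n_abn_dev} > "
                f"{self.n_scored - self.n_unfert})"
            )

    @property
    def n_fertilized(self) -> int:
        return self.n_scored - self.n_unfert

    @property
    def n_normal(self) -> int:
        return self.n_fertilized - self.n_tight - self.n_abn_dev


@dataclass(frozen=True)
class ScoredProportions:
    """Per-vial TF/AbnF/NF proportions; ``abnf_defined`` is False iff TF = 0."""

    tf: float
    abnf: float  # NaN when undefined
    nf: float
    abnf_defined: bool


@dataclass(frozen=True)
class TrialRecord:
    """One vial of one pair x treatment fertilization series."""

    site: str
    pair_id: str
    ph_treatment: str
    ph_measured: float
    vial_index: int
    sperm_conc: float
    counts: VialCounts

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise TrialValidationError(f"unknown site {self.site!r}; expected one of {SITES}")
        if str(self.ph_treatment) not in TREATMENT_LABELS:
            raise TrialValidationError(
                f"unknown pH treatment {self.ph_treatment!r}; expected one of {TREATMENT_LABELS}"
            )
        if self.sperm_conc <= 0:
            raise TrialValidationError(f"sperm_conc must be > 0, got {self.sperm_conc}")
        if self.vial_index < 1:
            raise TrialValidationError(f"vial_index must be >= 1, got {self.vial_index}")


@dataclass(frozen=True)
class DilutionSeries:
    """Serial 1:10 sperm dilution series.

    The hemocytometer count is of the stock solution (itself a 1:100
    predilution of dry sperm); each step transfers ``2.3 ml`` of the previous
    vial into treatment water for a ``25 ml``-vial total of ``23 ml``, i.e.
    one 1:10 factor per step.  Vial ``k`` (1-based) therefore holds
    ``stock * (1/step_factor)**k`` sperm per microliter.
    """

    hemocytometer_count: float
    predilution_factor: float = 100.0
    step_factor: float = 10.0
    step_volume_ratio: float = 2.3 / 23.0
    n_steps: int = 8

    def __post_init__(self) -> None:
        if self.hemocytometer_count <= 0:
            raise TrialValidationError("hemocytometer_count must be > 0")
        if self.predilution_factor <= 1 or self.step_factor <= 1:
            raise TrialValidationError("dilution factors must be > 1")
        if not (0 < self.step_volume_ratio < 1):
            raise TrialValidationError("step_volume_ratio must be in (0, 1)")
        if self.n_steps < 1:
            raise TrialValidationError("n_steps must be >= 1")


@dataclass(frozen=True)
class ExperimentDesign:
    """Site / pair / treatment layout of a fertilization experiment."""

    sites: tuple = (
        ("FC", 12, ("8.03", "7.76", "7.61")),
        ("BMR", 10, ("8.03", "7.76", "7.61")),
        ("SB", 12, ("8.03", "7.87", "7.76")),
    )
    stock_conc: float = 2e6
    n_steps: int = 8
    eggs_per_vial: int = 1000
    contact_time: float = 30.0
    n_scored: int = 200

    def __post_init__(self) -> None:
        for site, n_pairs, treatments in self.sites:
            if site not in SITES:
                raise TrialValidationError(f"unknown site {site!r}")
            if n_pairs < 1:
                raise TrialValidationError(f"{site}: n_pairs must be >= 1")
            if len(treatments) != len(set(treatments)):
                raise TrialValidationError(f"{site}: duplicate treatment labels")

    @property
    def n_vials(self) -> int:
        return sum(n for _, n, t in self.sites for _ in t) * self.n_steps


def score_vial(counts: VialCounts) -> ScoredProportions:
    """Compute TF, AbnF, NF for one vial of scored embryos.

    AbnF is undefined (NaN, flagged) when no egg fertilized; NF is then 0.
    """
    if counts.n_scored <= 0:
        raise TrialValidationError("n_scored must be > 0 to score a vial")
    tf = counts.n_fertilized / counts.n_scored
    if counts.n_fertilized == 0:
        return ScoredProportions(tf=0.0, abnf=math.nan, nf=0.0, abnf_defined=False)
    abnf = (counts.n_tight + counts.n_abn_dev) / counts.n_fertilized
    return ScoredProportions(tf=tf, abnf=abnf, nf=tf * (1.0 - abnf), abnf_defined=True)


def dilution_concentrations(series: DilutionSeries) -> list[float]:
    """Sperm concentrations (sperm/ul) in vials 1..n_steps of a serial dilution.

    The volume-based ratio (2.3/23 ml) and the nominal 1:10 step factor are
    the same number; the volume ratio is what is applied.
    """
    ratio = series.step_volume_ratio
    return [series.hemocytometer_count * ratio**k for k in range(1, series.n_steps + 1)]


def filter_analysis_window(
    records: Sequence[TrialRecord],
    response: str,
    windows: dict | None = None,
) -> list[TrialRecord]:
    """Keep records with sperm_conc strictly inside the response's open window."""
    windows = windows or ANALYSIS_WINDOWS
    if response not in windows:
        raise ValueError(
            f"unknown response {response!r}; expected one of {sorted(windows)}"
        )
    lo, hi = windows[response]
    return [r for r in records if lo < r.sperm_conc < hi]


def records_to_frame(records: Sequence[TrialRecord], scored: bool = False) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "site": r.site,
            "pair_id": r.pair_id,
            "ph_treatment": r.ph_treatment,
            "ph_measured": r.ph_measured,
            "vial_index": r.vial_index,
            "sperm_conc": r.sperm_conc,
            "n_scored": r.counts.n_scored,
            "n_unfert": r.counts.n_unfert,
            "n_tight": r.counts.n_tight,
            "n_abn_dev": r.counts.n_abn_dev,
        }
        if scored:
            p = score_vial(r.counts)
            row.update(tf=p.tf, abnf=p.abnf, nf=p.nf, abnf_defined=p.abnf_defined)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    missing = [c for c in TRIAL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            counts = VialCounts(
                n_scored=int(row["n_scored"]),
                n_unfert=int(row["n_unfert"]),
                n_tight=int(row["n_tight"]),
                n_abn_dev=int(row["n_abn_dev"]),
            )
            records.append(
                TrialRecord(
                    site=str(row["site"]),
                    pair_id=str(row["pair_id"]),
                    ph_treatment=str(row["ph_treatment"]),
                    ph_measured=float(row["ph_measured"]),
                    vial_index=int(row["vial_index"]),
                    sperm_conc=float(row["sperm_conc"]),
                    counts=counts,
                )
            )
        except TrialValidationError as exc:
            raise TrialValidationError(f"row {idx}: {exc}") from exc
    return records


def load_trials(path) -> list[TrialRecord]:
    """Load trial records from CSV (one vial per row, header required)."""
    df = pd.read_csv(path, dtype={"site": str, "pair_id": str, "ph_treatment": str},
                     float_precision="round_trip")
    return frame_to_records(df)


def write_trials(records: Sequence[TrialRecord], path, scored: bool = False) -> None:
    """Write trial records to CSV; ``scored=True`` appends tf/abnf/nf columns."""
    records_to_frame(records, scored=scored).to_csv(path, index=False)
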