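"""Domain types and CSV ingestion for country-by-quintile datasets.

A country is described by exactly five wealth quintiles, ordinal 1 (wealthiest)
through 5 (poorest).  Each quintile carries the under-five mortality rate
(U5MR, deaths per 1000 live births) and, optionally, current intervention
coverage, annual live births, pneumonia case-fatality rate and a simplex of
cause-of-death proportions.  Optional fields may be left unset on ingestion
and supplied later by configuration or the synthetic generator.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import UndefinedResultError, ValidationError

__all__ = [
    "QuintileProfile",
    "CountryDataset",
    "load_country_table",
    "write_country_table",
    "quintile_ratio",
    "reference_cost_table",
    "reference_datasets",
    "reference_effectiveness_table",
    "ANTIBIOTIC_COST",
]

#: Constant direct antibiotic cost, US$ per child treated, all strata.
ANTIBIOTIC_COST = 0.27

SIMPLEX_TOL = 1e-9
CAUSE_PREFIX = "cause:"


@dataclass(frozen=True)
class QuintileProfile:
    """One wealth stratum of one country.

    Parameters
    ----------
    country : str
        Country label.
    quintile : int
        Ordinal in 1..5; 1 = wealthiest, 5 = poorest.
    u5mr : float
        Under-five deaths per 1000 live births; non-negative.
    coverage : float, optional
        Fraction in [0, 1] of pneumonia episodes currently receiving
        community case management.
    births : float, optional
        Annual live births in the stratum; non-negative.
    cfr : float, optional
        Pneumonia deaths per episode, in (0, 1].
    cause_proportions : dict[str, float], optional
        Cause label -> fraction; must sum to 1 within 1e-9.
    """

    country: str
    quintile: int
    u5mr: float
    coverage: float | None = None
    births: float | None = None
    cfr: float | None = None
    cause_proportions: dict[str, float] | None = None

    def __post_init__(self):
        if not (isinstance(self.quintile, int) and 1 <= self.quintile <= 5):
            raise ValidationError(
                f"quintile must be an integer in 1..5, got {self.quintile!r}",
                field="quintile",
            )
        if not (self.u5mr >= 0 and math.isfinite(self.u5mr)):
            raise ValidationError(
                f"u5mr must be finite and >= 0, got {self.u5mr!r}", field="u5mr"
            )
        if self.coverage is not None and not (0.0 <= self.coverage <= 1.0):
            raise ValidationError(
                f"coverage must lie in [0, 1], got {self.coverage!r}",
                field="coverage",
            )
        if self.births is not None and not self.births >= 0:
            raise ValidationError(
                f"births must be >= 0, got {self.births!r}", field="births"
            )
        if self.cfr is not None and not (0.0 < self.cfr <= 1.0):
            raise ValidationError(
                f"cfr must lie in (0, 1], got {self.cfr!r}", field="cfr"
            )
        if self.cause_proportions is not None:
            total = 0.0
            for cause, p in self.cause_proportions.items():
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(
                        f"cause proportion for '{cause}' must lie in [0, 1], "
                        f"got {p!r}",
                        field=f"{CAUSE_PREFIX}{cause}",
                    )
                total += p
            if abs(total - 1.0) > SIMPLEX_TOL:
                raise ValidationError(
                    f"cause proportions must sum to 1 (got {total!r})",
                    field="cause_proportions",
                )


@dataclass(frozen=True)
class CountryDataset:
    """Exactly five quintile profiles for one country, ordered Q1 -> Q5."""

    country: str
    quintiles: tuple[QuintileProfile, ...]
    overall_u5mr: float | None = None

    def __post_init__(self):
        if len(self.quintiles) != 5:
            raise ValidationError(
                f"expected exactly 5 quintiles for '{self.country}', "
                f"got {len(self.quintiles)}"
            )
        ordinals = [q.quintile for q in self.quintiles]
        if ordinals != [1, 2, 3, 4, 5]:
            raise ValidationError(
                f"quintiles must be ordered 1..5, got {ordinals}"
            )
        for q in self.quintiles:
            if q.country != self.country:
                raise ValidationError(
                    f"quintile country '{q.country}' does not match dataset "
                    f"country '{self.country}'"
                )
        object.__setattr__(self, "quintiles", tuple(self.quintiles))

    def quintile(self, ordinal: int) -> QuintileProfile:
        return self.quintiles[ordinal - 1]

    @property
    def u5mr(self) -> list[float]:
        return [q.u5mr for q in self.quintiles]

    @property
    def coverage(self) -> list[float | None]:
        return [q.coverage for q in self.quintiles]

    @property
    def births(self) -> list[float | None]:
        return [q.births for q in self.quintiles]

    def with_fields(self, **per_quintile) -> "CountryDataset":
        """Return a copy with per-quintile fields replaced.

        Each keyword maps a QuintileProfile field name to a length-5 sequence
        of new values (Q1 -> Q5).
        """
        new = []
        for i, q in enumerate(self.quintiles):
            updates = {k: v[i] for k, v in per_quintile.items()}
            new.append(replace(q, **updates))
        return CountryDataset(self.country, tuple(new), self.overall_u5mr)

    def to_json(self) -> str:
        """Serialize the validated dataset for downstream stages."""
        payload = {
            "country": self.country,
            "overall_u5mr": self.overall_u5mr,
            "quintiles": [
                {
                    "quintile": q.quintile,
                    "u5mr": q.u5mr,
                    "coverage": q.coverage,
                    "births": q.births,
                    "cfr": q.cfr,
                    "cause_proportions": q.cause_proportions,
                }
                for q in self.quintiles
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("country", "quintile", "u5mr")
_OPTIONAL_COLUMNS = ("coverage", "births", "cfr")


def _parse_number(raw, row_no, col):
    if raw is None or raw == "":
        return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"non-numeric cell {raw!r}", row=row_no, field=col
        ) from None


def load_country_table(path) -> CountryDataset:
    """Read a validated :class:`CountryDataset` from a CSV file.

    Expected header: ``country,quintile,u5mr[,coverage,births,cfr,
    cause:<label>...]``.  Comma separated, UTF-8, dot decimal separator.
    Blank optional cells are treated as unset.

    Raises
    ------
    ValidationError
        On missing columns, non-numeric cells, quintile count != 5 or a
        cause-proportion simplex violation, naming the offending row/field.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"empty CSV file: {path}")
        for col in _REQUIRED_COLUMNS:
            if col not in reader.fieldnames:
                raise ValidationError(f"missing column '{col}'", field=col)
        cause_cols = [
            c for c in reader.fieldnames if c.startswith(CAUSE_PREFIX)
        ]
        profiles = []
        country = None
        for row_no, row in enumerate(reader, start=2):
            if country is None:
                country = row["country"]
            elif row["country"] != country:
                raise ValidationError(
                    f"inconsistent country label {row['country']!r} "
                    f"(expected {country!r})",
                    row=row_no,
                    field="country",
                )
            q_raw = _parse_number(row["quintile"], row_no, "quintile")
            if q_raw is None or q_raw != int(q_raw):
                raise ValidationError(
                    f"quintile must be an integer 1..5, got {row['quintile']!r}",
                    row=row_no,
                    field="quintile",
                )
            kwargs = {"country": country, "quintile": int(q_raw)}
            kwargs["u5mr"] = _parse_number(row["u5mr"], row_no, "u5mr")
            if kwargs["u5mr"] is None:
                raise ValidationError("missing u5mr", row=row_no, field="u5mr")
            for col in _OPTIONAL_COLUMNS:
                if col in row:
                    kwargs[col] = _parse_number(row.get(col), row_no, col)
            if cause_cols:
                causes = {}
                for col in cause_cols:
                    v = _parse_number(row.get(col), row_no, col)
                    if v is not None:
                        causes[col[len(CAUSE_PREFIX):]] = v
                if causes:
                    kwargs["cause_proportions"] = causes
            try:
                profiles.append(QuintileProfile(**kwargs))
            except ValidationError as exc:
                raise ValidationError(str(exc), row=row_no) from exc
    if len(profiles) != 5:
        raise ValidationError(
            f"expected exactly 5 quintile rows, got {len(profiles)}"
        )
    profiles.sort(key=lambda q: q.quintile)
    return CountryDataset(country=country, quintiles=tuple(profiles))


def write_country_table(dataset: CountryDataset, path) -> None:
    """Write a dataset back to the CSV dialect accepted by
    :func:`load_country_table` (round-trips all fields)."""
    causes = sorted(
        {
            c
            for q in dataset.quintiles
            if q.cause_proportions
            for c in q.cause_proportions
        }
    )
    header = list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS) + [
        f"{CAUSE_PREFIX}{c}" for c in causes
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for q in dataset.quintiles:
            row = [
                q.country,
                q.quintile,
                repr(q.u5mr),
                "" if q.coverage is None else repr(q.coverage),
                "" if q.births is None else repr(q.births),
                "" if q.cfr is None else repr(q.cfr),
            ]
            for c in causes:
                v = (q.cause_proportions or {}).get(c)
                row.append("" if v is None else repr(v))
            writer.writerow(row)


def quintile_ratio(dataset: CountryDataset) -> float:
    """U5MR of the poorest quintile divided by that of the wealthiest.

    A value of 1 indicates perfect equity; larger values mean the poorest
    fare worse.

    Raises
    ------
    UndefinedResultError
        If the wealthiest quintile's U5MR is zero.
    """
    q1 = dataset.quintile(1).u5mr
    q5 = dataset.quintile(5).u5mr
    if q1 == 0:
        raise UndefinedResultError(
            f"quintile ratio undefined: Q1 u5mr is 0 for '{dataset.country}'"
        )
    return q5 / q1


# ---------------------------------------------------------------------------
# Bundled reference tables
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return importlib.resources.files("equiscale.data") / name


def reference_cost_table() -> pd.DataFrame:
    """The bundled 30-cell cost calibration table.

    Columns: country, column ('overall' or '1'..'5'), u5mr,
    antibiotic_cost, nonantibiotic_cost, total_cost.  Covers five countries
    times six columns (overall plus five quintiles).
    """
    with importlib.resources.as_file(_data_path("country_costs.csv")) as p:
        return pd.read_csv(p, dtype={"column": str})


def reference_datasets() -> dict[str, CountryDataset]:
    """Country datasets built from the bundled reference table.

    Only ``u5mr`` and ``overall_u5mr`` are populated; coverage, births, CFR
    and cause proportions are left unset, to be supplied by configuration or
    the synthetic generator.
    """
    table = reference_cost_table()
    out = {}
    for country, grp in table.groupby("country", sort=False):
        overall = float(
            grp.loc[grp["column"] == "overall", "u5mr"].iloc[0]
        )
        quintiles = tuple(
            QuintileProfile(
                country=country,
                quintile=int(row["column"]),
                u5mr=float(row["u5mr"]),
            )
            for _, row in grp[grp["column"] != "overall"].iterrows()
        )
        out[country] = CountryDataset(
            country=country, quintiles=quintiles, overall_u5mr=overall
        )
    return out


def reference_effectiveness_table() -> pd.DataFrame:
    """The bundled ten-row effectiveness study table.

    Columns: location, year, u5mr, effectiveness (percent).  The final row
    is the (u5mr 0, effectiveness 100) anchor point.
    """
    with importlib.resources.as_file(
        _data_path("effectiveness_studies.csv")
    ) as p:
        return pd.read_csv(p)
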