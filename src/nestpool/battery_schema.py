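"""Data model for neuropsychological outcomes nested within cognitive domains.

A battery table is a long-format :class:`pandas.DataFrame` (one row per
subject per visit wave) whose outcome columns are grouped into cognitive
domains by a :class:`DomainMap`.  The bundled default map nests 22 outcome
measures in 7 domains (primary memory, perceptual speed, verbal episodic
memory, visuospatial function, visual episodic memory, verbal ability,
interference); timed measures carry orientation ``-1`` ("lower is better")
and are sign-flipped before standardization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Domain",
    "DomainMap",
    "ValidationReport",
    "default_domain_map",
    "load_domain_map",
    "save_domain_map",
    "validate_battery",
    "GROUP_LABELS",
    "WAVES",
    "METADATA_COLUMNS",
]

#: group labels accepted in the ``group`` column
GROUP_LABELS = ("exposed", "control")

#: visit waves: 0 = baseline, 1 = 18 months, 2 = 36 months
WAVES = (0, 1, 2)

#: non-outcome columns of a battery table
METADATA_COLUMNS = (
    "subject_id",
    "group",
    "wave",
    "age_baseline",
    "sex",
    "wtar_iq",
    "education_band",
    "apoe_e4",
    "loc_minutes",
    "age_first_injury",
)


@dataclass(frozen=True)
class Domain:
    """One cognitive domain and the outcome measures nested inside it."""

    domain_id: str
    label: str
    outcomes: tuple[str, ...]


@dataclass(frozen=True)
class DomainMap:
    """Ordered nesting of outcome measures within cognitive domains.

    Parameters
    ----------
    domains
        Ordered domains; every outcome id appears in exactly one domain.
    orientation
        outcome_id -> +1 or -1.  ``-1`` means larger raw values indicate
        *worse* performance (e.g. completion times) and the column is
        sign-flipped before scaling so that, after preprocessing, larger
        always means better.
    """

    domains: tuple[Domain, ...]
    orientation: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for dom in self.domains:
            if len(dom.outcomes) == 0:
                raise ValueError(f"domain {dom.domain_id!r} has no outcomes")
            for out in dom.outcomes:
                if out in seen:
                    raise ValueError(
                        f"outcome {out!r} listed under both "
                        f"{seen[out]!r} and {dom.domain_id!r}"
                    )
                seen[out] = dom.domain_id
        for out, flag in self.orientation.items():
            if out not in seen:
                raise ValueError(f"orientation given for unknown outcome {out!r}")
            if flag not in (1, -1):
                raise ValueError(f"orientation for {out!r} must be +1 or -1, got {flag!r}")

    # -- look-ups ---------------------------------------------------------
    @property
    def outcome_ids(self) -> tuple[str, ...]:
        """All outcome ids, in domain order."""
        return tuple(o for d in self.domains for o in d.outcomes)

    @property
    def domain_ids(self) -> tuple[str, ...]:
        return tuple(d.domain_id for d in self.domains)

    @property
    def n_outcomes(self) -> int:
        return len(self.outcome_ids)

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def domain_of(self, outcome_id: str) -> str:
        for d in self.domains:
            if outcome_id in d.outcomes:
                return d.domain_id
        raise KeyError(outcome_id)

    def domain_index_of_outcome(self) -> dict[str, int]:
        """outcome_id -> positional index of its domain."""
        out = {}
        for i, d in enumerate(self.domains):
            for o in d.outcomes:
                out[o] = i
        return out

    def orientation_of(self, outcome_id: str) -> int:
        return int(self.orientation.get(outcome_id, 1))

    def to_dict(self) -> dict:
        return {
            "domains": [
                {"domain_id": d.domain_id, "label": d.label, "outcomes": list(d.outcomes)}
                for d in self.domains
            ],
            "orientation": {k: int(v) for k, v in self.orientation.items() if v == -1},
        }


def _map_from_dict(raw: dict) -> DomainMap:
    try:
        domains = tuple(
            Domain(
                domain_id=str(d["domain_id"]),
                label=str(d.get("label", d["domain_id"])),
                outcomes=tuple(str(o) for o in d["outcomes"]),
            )
            for d in raw["domains"]
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"domain map does not match the documented schema: {exc}") from exc
    orientation = {str(k): int(v) for k, v in (raw.get("orientation") or {}).items()}
    return DomainMap(domains=domains, orientation=orientation)


def load_domain_map(path: str | Path) -> DomainMap:
    """Load a :class:`DomainMap` from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return _map_from_dict(raw)


def save_domain_map(dm: DomainMap, path: str | Path) -> None:
    """Write a :class:`DomainMap` as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = dm.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def default_domain_map() -> DomainMap:
    """The bundled 7-domain / 22-outcome battery nesting."""
    with resources.files("nestpool.data").joinpath("domains.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return _map_from_dict(raw)


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """Result of checking a battery table against the schema invariants."""

    errors: list[tuple[str, str]]
    warnings: list[str]
    n_subjects: int
    n_rows: int
    missingness: pd.DataFrame  # outcomes x waves, fraction missing

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "errors": [{"rule": r, "keys": k} for r, k in self.errors],
            "warnings": list(self.warnings),
            "n_subjects": self.n_subjects,
            "n_rows": self.n_rows,
            "missingness": {
                str(out): {str(w): float(v) for w, v in row.items()}
                for out, row in self.missingness.iterrows()
            },
        }


def validate_battery(table: pd.DataFrame, dmap: DomainMap) -> ValidationReport:
    """Check a long-format battery table against the schema invariants.

    Problems are reported, never raised.  The report is deterministic and
    invariant to row order.
    """
    errors: list[tuple[str, str]] = []
    warnings: list[str] = []

    missing_cols = [c for c in ("subject_id", "group", "wave") if c not in table.columns]
    if missing_cols:
        errors.append(("missing_columns", ",".join(missing_cols)))
        miss = pd.DataFrame(index=list(dmap.outcome_ids), columns=list(WAVES), dtype=float)
        return ValidationReport(errors, warnings, 0, len(table), miss)

    outcome_cols = [o for o in dmap.outcome_ids if o in table.columns]
    absent = [o for o in dmap.outcome_ids if o not in table.columns]
    for o in absent:
        errors.append(("outcome_column_absent", o))

    bad_group = sorted(set(table["group"]) - set(GROUP_LABELS))
    for g in bad_group:
        errors.append(("unknown_group_label", str(g)))
    bad_wave = sorted(set(table["wave"]) - set(WAVES))
    for w in bad_wave:
        errors.append(("unknown_wave", str(w)))

    dup = table.groupby(["subject_id", "wave"], sort=True).size()
    for (sid, wave), n in dup[dup > 1].items():
        errors.append(("duplicate_subject_wave", f"{sid}@wave{wave} x{n}"))

    # exposure features only for exposed subjects
    for col in ("loc_minutes", "age_first_injury"):
        if col in table.columns:
            bad = table.loc[
                (table["group"] == "control") & table[col].notna(), "subject_id"
            ]
            for sid in sorted(set(bad)):
                errors.append((f"{col}_on_control", str(sid)))

    if "loc_minutes" in table.columns:
        nonpos = table.loc[table["loc_minutes"].notna() & (table["loc_minutes"] <= 0), "subject_id"]
        for sid in sorted(set(nonpos)):
            errors.append(("nonpositive_loc_minutes", str(sid)))

    if outcome_cols:
        all_missing = table[outcome_cols].isna().all(axis=1)
        for sid, wave in (
            table.loc[all_missing, ["subject_id", "wave"]].sort_values(["subject_id", "wave"]).itertuples(index=False)
        ):
            errors.append(("row_without_outcomes", f"{sid}@wave{wave}"))

    n_subjects = table["subject_id"].nunique()
    miss = pd.DataFrame(index=list(dmap.outcome_ids), columns=list(WAVES), dtype=float)
    for w in WAVES:
        sub = table[table["wave"] == w]
        for o in dmap.outcome_ids:
            if o in table.columns and len(sub):
                miss.loc[o, w] = float(sub[o].isna().mean())
            else:
                miss.loc[o, w] = float("nan")

    if n_subjects and "wave" in table.columns:
        baseline = set(table.loc[table["wave"] == 0, "subject_id"])
        orphans = set(table["subject_id"]) - baseline
        if orphans:
            warnings.append(f"{len(orphans)} subject(s) have no baseline row")

    errors.sort()
    return ValidationReport(errors, warnings, int(n_subjects), int(len(table)), miss)


def read_battery_csv(path: str | Path) -> pd.DataFrame:
    """Read a battery table from CSV (UTF-8, empty cells = missing)."""
    return pd.read_csv(path)


def write_battery_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
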