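"""Serialization and run metadata.

Cohorts travel as plain CSV (one header line, UTF-8, 17-significant-digit
floats so values round-trip exactly); configurations and reports as JSON.
Every output file embeds :class:`RunMetadata` — tool version, a stable
digest of the canonicalized configuration, and the master seed — so a
result can always be traced back to the exact run that produced it.
Metadata deliberately carries no wall-clock timestamp: two runs with the
same configuration and seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .model import COMPONENTS, ComponentSpec, DEFAULT_COMPONENT_SPECS
from .simulate import SEXES, SPORTS, Cohort
from .study import StudyConfig, StudyReport

__all__ = [
    "COHORT_COLUMNS",
    "RunMetadata",
    "read_cohort",
    "write_cohort",
    "read_config",
    "write_config",
    "write_report",
    "write_roc_csv",
    "read_component_specs",
    "write_component_specs",
    "CohortFormatError",
]

try:
    _VERSION = version("wase")
except PackageNotFoundError:  # pragma: no cover - running from a source tree
    _VERSION = "unknown"

COHORT_COLUMNS = (
    ["id", "age", "sex", "sport", "train_hours"]
    + [f"{c}_true" for c in COMPONENTS]
    + list(COMPONENTS)
    + ["wase", "p_injury", "injured"]
)

_METADATA_PREFIX = "# wase-metadata: "


class CohortFormatError(ValueError):
    """Raised when a cohort CSV violates the documented format."""


@dataclass(frozen=True)
class RunMetadata:
    """Provenance stamp embedded in every output file."""

    tool_version: str = _VERSION
    config_digest: str = ""
    seed: int | None = None
    substreams: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tool_version": self.tool_version,
            "config_digest": self.config_digest,
            "seed": self.seed,
            "substreams": self.substreams,
        }

    @classmethod
    def for_cohort(cls, cohort: Cohort) -> "RunMetadata":
        names = ("demographics", "components", "noise", "outcomes")
        children = np.random.SeedSequence(cohort.seed).spawn(len(names))
        return cls(
            config_digest=cohort.config_digest,
            seed=cohort.seed,
            substreams={
                n: [int(x) for x in ss.generate_state(1)]
                for n, ss in zip(names, children)
            },
        )


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV with an embedded metadata comment line."""
    path = Path(path)
    meta = RunMetadata.for_cohort(cohort).to_dict()
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(_METADATA_PREFIX + json.dumps(meta, sort_keys=True) + "\n")
        cohort.df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")


def _row_error(idx: int, message: str) -> CohortFormatError:
    # +2: header line plus 1-based counting (metadata comment not counted)
    return CohortFormatError(f"row {idx + 1}: {message}")


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort CSV written by :func:`write_cohort`.

    Errors name the offending column or data row.  Score/outcome columns may
    be empty (not yet computed); present values are validated.
    """
    path = Path(path)
    seed = 0
    digest = ""
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith(_METADATA_PREFIX):
        meta = json.loads(first[len(_METADATA_PREFIX):])
        seed = meta.get("seed") or 0
        digest = meta.get("config_digest", "")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise CohortFormatError(f"unknown column(s): {', '.join(unknown)}")
    df = df[COHORT_COLUMNS]

    numeric = (
        ["age", "train_hours"]
        + [f"{c}_true" for c in COMPONENTS]
        + list(COMPONENTS)
        + ["wase", "p_injury"]
    )
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise _row_error(int(bad.idxmax()), f"non-numeric value in column {col!r}")
        df[col] = coerced

    ids = pd.to_numeric(df["id"], errors="coerce")
    if ids.isna().any():
        raise _row_error(int(ids.isna().idxmax()), "non-integer id")
    df["id"] = ids.astype(int)
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(df["id"].to_numpy(), expected):
        raise CohortFormatError("ids must be unique and contiguous from 1")

    for col, domain in (("sex", SEXES), ("sport", SPORTS)):
        bad = ~df[col].isin(domain)
        if bad.any():
            raise _row_error(
                int(bad.idxmax()),
                f"value {df[col][bad.idxmax()]!r} in column {col!r} not in {domain}",
            )

    for col in COMPONENTS + tuple(f"{c}_true" for c in COMPONENTS):
        vals = df[col]
        bad = vals.notna() & ((vals < 0) | (vals > 0.5))
        if bad.any():
            raise _row_error(
                int(bad.idxmax()), f"component {col!r} outside plausibility [0, 0.5]"
            )

    injured = df["injured"]
    bad = injured.notna() & ~injured.isin((0, 1, 0.0, 1.0))
    if bad.any():
        raise _row_error(int(bad.idxmax()), "injured must be 0 or 1")
    for col in ("wase", "p_injury"):
        vals = df[col]
        bad = vals.notna() & ((vals < 0) | (vals > 1))
        if bad.any():
            raise _row_error(int(bad.idxmax()), f"{col} must lie in [0, 1]")

    return Cohort(df=df, seed=int(seed), config_digest=digest)


def write_config(config: StudyConfig, path: str | Path) -> None:
    payload = {
        "metadata": RunMetadata(
            config_digest=config.population.digest(), seed=config.seed
        ).to_dict(),
        "study": config.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_config(path: str | Path) -> StudyConfig:
    payload = json.loads(Path(path).read_text())
    if "study" in payload:
        payload = payload["study"]
    return StudyConfig.from_dict(payload)


def write_report(report: StudyReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the JSON + markdown study report (and ROC CSV) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = RunMetadata(
        config_digest=report.config.population.digest(), seed=report.config.seed
    )
    payload = {"metadata": meta.to_dict(), "report": report.to_dict()}
    paths = {
        "json": out / "study_report.json",
        "markdown": out / "study_report.md",
    }
    paths["json"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    paths["markdown"].write_text(
        f"<!-- {json.dumps(meta.to_dict(), sort_keys=True)} -->\n"
        + report.to_markdown()
    )
    return paths


def write_roc_csv(roc, path: str | Path, metadata: RunMetadata | None = None) -> None:
    """Two-column (fpr, tpr) CSV export of an ROC curve."""
    path = Path(path)
    meta = (metadata or RunMetadata()).to_dict()
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(_METADATA_PREFIX + json.dumps(meta, sort_keys=True) + "\n")
        roc.to_frame().to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")


def write_component_specs(
    specs=DEFAULT_COMPONENT_SPECS, path: str | Path = "component_specs.csv"
) -> None:
    rows = [
        {
            "component": s.name,
            "weight": s.weight,
            "normal_lo": s.normal_lo,
            "normal_hi": s.normal_hi,
            "risk_threshold": s.risk_threshold,
        }
        for s in specs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_component_specs(path: str | Path) -> tuple[ComponentSpec, ...]:
    df = pd.read_csv(path)
    required = {"component", "weight", "normal_lo", "normal_hi", "risk_threshold"}
    missing = required - set(df.columns)
    if missing:
        raise CohortFormatError(f"missing column(s): {', '.join(sorted(missing))}")
    return tuple(
        ComponentSpec(
            name=row["component"],
            weight=row["weight"],
            normal_lo=row["normal_lo"],
            normal_hi=row["normal_hi"],
            risk_threshold=row["risk_threshold"],
        )
        for _, row in df.iterrows()
    )


def compute_digest(obj: dict) -> str:
    """Stable short hash of a JSON-serializable object."""
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:12]
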