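"""Reading and writing cohort tables, decisions and structured reports.

Cohort tables are delimited text (comma or tab, auto-detected from the
header line, overridable) with one row per patient.  Mandatory columns are
``patient_id``, the five microsatellite markers (``msi_bat26`` ...
``msi_nr27``: stable|unstable|failed) and the four IHC proteins
(``ihc_mlh1`` ... ``ihc_pms2``: retained|lost|unreliable).  Optional
columns carry age, MS-MLPA probe ratios (``meth_tumor_probe3`` etc., blank
= not measured), pathology fields, family-history flags and a packed
``germline_results`` column (``GENE|outcome|variant`` entries joined by
``;``).  Enum tokens are case-insensitive on input and canonical
lower-case on output; unknown columns pass through untouched.
"""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .assay_calls import IhcPanel, MethylationMeasurement, MsiMarkerPanel, Tissue
from .cohort_stats import AssociationResult, CascadeSummary, predictive_frequency
from .synthetic_cohort import CohortTable, PatientRecord
from .triage import GermlineResult, TriageDecision

__all__ = [
    "PipelineConfig",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "write_decisions",
    "build_report",
    "write_report",
    "load_config",
    "round_half_up",
    "file_checksum",
]

MSI_COLUMNS = ["msi_bat26", "msi_bat25", "msi_nr21", "msi_nr24", "msi_nr27"]
IHC_COLUMNS = ["ihc_mlh1", "ihc_msh2", "ihc_msh6", "ihc_pms2"]
METH_COLUMNS = [
    "meth_tumor_probe3", "meth_tumor_probe4",
    "meth_blood_probe3", "meth_blood_probe4",
]
MANDATORY_COLUMNS = ["patient_id", *MSI_COLUMNS, *IHC_COLUMNS]
OPTIONAL_COLUMNS = [
    "age", *METH_COLUMNS, "germline_results", "stage", "histology",
    "grade_figo", "myometrial_invasion", "til", "lvi", "lus",
    "synchronous_ovarian", "synchronous_tumor", "family_history_known",
    "rbg", "amii",
]


class PipelineConfig(BaseModel):
    """Tunable knobs of the screening pipeline."""

    msi_min_informative: int = Field(default=3, ge=1, le=5)
    methylation_threshold: float = Field(default=0.15, gt=0.0, lt=1.0)
    ci_method: Literal["woolf", "exact", "auto"] = "auto"
    continuity_correction: bool = False
    zero_cell_correction: bool = False
    decimals: int = Field(default=1, ge=0)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig(**data)


class CohortValidationError(ValueError):
    """Row-level validation failures, each tagged with its line number."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__(
            "cohort validation failed:\n" + "\n".join(f"  - {e}" for e in errors)
        )


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at fixed decimals (printing convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _detect_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


_TRUE = {"true", "yes", "y", "1"}
_FALSE = {"false", "no", "n", "0"}


def _parse_bool(value: str, where: str) -> Optional[bool]:
    v = value.strip().lower()
    if v == "":
        return None
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"{where}: cannot parse boolean {value!r}")


def _parse_float(value: str, where: str) -> Optional[float]:
    v = value.strip()
    if v == "":
        return None
    try:
        return float(v)
    except ValueError:
        raise ValueError(f"{where}: cannot parse number {value!r}") from None


def _parse_germline(value: str, where: str) -> tuple[GermlineResult, ...]:
    v = value.strip()
    if not v:
        return ()
    results = []
    for entry in v.split(";"):
        parts = entry.split("|")
        if len(parts) not in (2, 3):
            raise ValueError(
                f"{where}: germline entry {entry!r} is not GENE|outcome[|variant]"
            )
        gene, outcome = parts[0], parts[1]
        variant = parts[2] if len(parts) == 3 else ""
        results.append(GermlineResult(gene=gene, outcome=outcome.lower(),
                                      variant_label=variant))
    return tuple(results)


def read_cohort(path: str | Path, dialect: Optional[str] = None) -> CohortTable:
    """Read a cohort table, validating every row.

    ``dialect`` is ``"csv"`` or ``"tsv"``; by default the separator is
    sniffed from the header line.  All row-level problems are collected
    and raised together as :class:`CohortValidationError` with line
    numbers; missing mandatory columns fail immediately.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = {"csv": ",", "tsv": "\t"}.get(dialect) if dialect else _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(
            [f"missing mandatory column(s): {', '.join(missing)}"]
        )
    extra_cols = [
        c for c in df.columns if c not in MANDATORY_COLUMNS + OPTIONAL_COLUMNS
    ]

    patients: list[PatientRecord] = []
    errors: list[str] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        row = dict(zip(df.columns, row))
        where = f"line {i}"
        try:
            pid = row["patient_id"].strip()
            if not pid:
                raise ValueError(f"{where}: empty patient_id")
            if pid in seen_ids:
                raise ValueError(f"{where}: duplicate patient_id {pid!r}")
            seen_ids.add(pid)
            msi = MsiMarkerPanel(*(row[c] for c in MSI_COLUMNS))
            ihc = IhcPanel(*(row[c] for c in IHC_COLUMNS))
            probes = {
                c: _parse_float(row.get(c, ""), f"{where} column {c}")
                for c in METH_COLUMNS
            }
            meth_tumor = meth_blood = None
            if probes["meth_tumor_probe3"] is not None or probes["meth_tumor_probe4"] is not None:
                meth_tumor = MethylationMeasurement(
                    probes["meth_tumor_probe3"], probes["meth_tumor_probe4"],
                    tissue=Tissue.TUMOR,
                )
            if probes["meth_blood_probe3"] is not None or probes["meth_blood_probe4"] is not None:
                meth_blood = MethylationMeasurement(
                    probes["meth_blood_probe3"], probes["meth_blood_probe4"],
                    tissue=Tissue.BLOOD,
                )
            age_val = _parse_float(row.get("age", ""), f"{where} column age")
            grade = _parse_float(row.get("grade_figo", ""), f"{where} column grade_figo")
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    age=int(age_val) if age_val is not None else -1,
                    msi=msi,
                    ihc=ihc,
                    meth_tumor=meth_tumor,
                    meth_blood=meth_blood,
                    germline=_parse_germline(
                        row.get("germline_results", ""), where
                    ),
                    stage=row.get("stage", "").strip() or None,
                    histology=row.get("histology", "").strip() or None,
                    grade_figo=int(grade) if grade is not None else None,
                    myometrial_invasion=row.get("myometrial_invasion", "").strip() or None,
                    til=_parse_bool(row.get("til", ""), f"{where} column til"),
                    lvi=_parse_bool(row.get("lvi", ""), f"{where} column lvi"),
                    lus=_parse_bool(row.get("lus", ""), f"{where} column lus"),
                    synchronous_ovarian=_parse_bool(
                        row.get("synchronous_ovarian", ""),
                        f"{where} column synchronous_ovarian",
                    ),
                    synchronous_tumor=row.get("synchronous_tumor", "").strip() or None,
                    family_history_known=bool(
                        _parse_bool(
                            row.get("family_history_known", ""),
                            f"{where} column family_history_known",
                        )
                    ),
                    rbg=_parse_bool(row.get("rbg", ""), f"{where} column rbg"),
                    amii=_parse_bool(row.get("amii", ""), f"{where} column amii"),
                    extra={c: row[c] for c in extra_cols},
                )
            )
        except ValueError as exc:
            msg = str(exc)
            errors.append(msg if msg.startswith("line ") else f"{where}: {msg}")
    if errors:
        raise CohortValidationError(errors)
    return CohortTable(patients=tuple(patients), provenance={"source": str(path)})


def _fmt_bool(v: Optional[bool]) -> str:
    return "" if v is None else ("yes" if v else "no")


def _fmt_germline(results: Sequence[GermlineResult]) -> str:
    return ";".join(
        f"{r.gene}|{r.outcome.value}|{r.variant_label}" for r in results
    )


def cohort_to_frame(cohort: CohortTable) -> pd.DataFrame:
    """Flatten a cohort into the canonical column layout."""
    rows = []
    for p in cohort:
        meth = {c: "" for c in METH_COLUMNS}
        if p.meth_tumor is not None:
            meth["meth_tumor_probe3"] = "" if p.meth_tumor.probe_mlh1_3 is None else p.meth_tumor.probe_mlh1_3
            meth["meth_tumor_probe4"] = "" if p.meth_tumor.probe_mlh1_4 is None else p.meth_tumor.probe_mlh1_4
        if p.meth_blood is not None:
            meth["meth_blood_probe3"] = "" if p.meth_blood.probe_mlh1_3 is None else p.meth_blood.probe_mlh1_3
            meth["meth_blood_probe4"] = "" if p.meth_blood.probe_mlh1_4 is None else p.meth_blood.probe_mlh1_4
        rows.append({
            "patient_id": p.patient_id,
            "age": p.age if p.age >= 0 else "",
            **{c: getattr(p.msi, c.removeprefix("msi_")).value for c in MSI_COLUMNS},
            **{c: getattr(p.ihc, c.removeprefix("ihc_")).value for c in IHC_COLUMNS},
            **meth,
            "germline_results": _fmt_germline(p.germline),
            "stage": p.stage or "",
            "histology": p.histology or "",
            "grade_figo": p.grade_figo if p.grade_figo is not None else "",
            "myometrial_invasion": p.myometrial_invasion or "",
            "til": _fmt_bool(p.til),
            "lvi": _fmt_bool(p.lvi),
            "lus": _fmt_bool(p.lus),
            "synchronous_ovarian": _fmt_bool(p.synchronous_ovarian),
            "synchronous_tumor": p.synchronous_tumor or "",
            "family_history_known": _fmt_bool(p.family_history_known),
            "rbg": _fmt_bool(p.rbg),
            "amii": _fmt_bool(p.amii),
            **p.extra,
        })
    return pd.DataFrame(rows)


def write_cohort(cohort: CohortTable, path: str | Path,
                 dialect: Optional[str] = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab", ".txt") else "csv"
    sep = "\t" if dialect == "tsv" else ","
    cohort_to_frame(cohort).to_csv(path, sep=sep, index=False)


def decisions_to_frame(decisions: Sequence[TriageDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [d.patient_id or "" for d in decisions],
            "mmr_status": [d.mmr.value for d in decisions],
            "label": [d.label.value for d in decisions],
            "gene_plan": [";".join(d.gene_plan) for d in decisions],
            "rationale": [";".join(d.rationale) for d in decisions],
        }
    )


def write_decisions(decisions: Sequence[TriageDecision], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    decisions_to_frame(decisions).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# structured report


def _pct(num: int, den: int, decimals: int) -> float:
    return round_half_up(100.0 * num / den, decimals)


def build_report(
    summary: CascadeSummary,
    associations: Optional[dict[str, dict]] = None,
    decisions: Optional[Sequence[TriageDecision]] = None,
    config: Optional[PipelineConfig] = None,
    input_checksum: Optional[str] = None,
) -> dict:
    """Assemble the machine-readable screening report.

    Every percentage in the report is recomputable from the counts that
    sit next to it.
    """
    config = config or PipelineConfig()
    nd = config.decimals
    cascade = {
        "n_total": summary.n_total,
        "n_ihc_loss": summary.n_ihc_loss,
        "n_msi": summary.n_msi,
        "n_concordant": summary.n_concordant,
        "n_discordant": summary.n_discordant,
        "pct_concordant": _pct(summary.n_concordant, summary.n_total, nd),
        "n_mmr_deficient": summary.n_mmr_deficient,
        "pct_mmr_deficient": _pct(summary.n_mmr_deficient, summary.n_total, nd),
        "n_mlh1_loss": summary.n_mlh1_loss,
        "pct_mlh1_loss": _pct(summary.n_mlh1_loss, summary.n_total, nd),
        "n_mlh1_methylated": summary.n_mlh1_methylated,
        "n_sporadic_methylated": summary.n_sporadic_methylated,
        "n_epimutation_suspected": summary.n_epimutation_suspected,
        "n_suspected": summary.n_suspected,
        "pct_suspected": _pct(summary.n_suspected, summary.n_total, nd),
        "n_pending": summary.n_pending,
        "n_unresolvable": summary.n_unresolvable,
        "n_tested": summary.n_tested,
        "n_pathogenic": summary.n_pathogenic,
        "pattern_counts": dict(summary.pattern_counts),
        "prevalence_observed_pct": _pct(summary.n_pathogenic, summary.n_total, nd),
    }
    if summary.n_mlh1_loss:
        cascade["pct_mlh1_methylated_of_loss"] = _pct(
            summary.n_mlh1_methylated, summary.n_mlh1_loss, nd
        )
    if summary.n_tested:
        cascade["pct_pathogenic_of_tested"] = _pct(
            summary.n_pathogenic, summary.n_tested, nd
        )
        cascade["predictive_frequency_pct"] = round_half_up(
            100.0 * predictive_frequency(summary), nd
        )
    report = {
        "provenance": {
            "software": f"lynchtriage {__version__}",
            "config": config.model_dump(),
            "input_checksum": input_checksum,
        },
        "cascade": cascade,
    }
    if associations is not None:
        report["associations"] = associations
    if decisions is not None:
        report["decisions"] = decisions_to_frame(decisions).to_dict(orient="records")
    return report


def association_to_dict(name: str, table, result: AssociationResult,
                        decimals: int = 2) -> dict:
    return {
        "variable": name,
        "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "odds_ratio": round_half_up(result.odds_ratio, decimals)
        if result.odds_ratio != float("inf") else None,
        "ci_low": round_half_up(result.ci_low, decimals),
        "ci_high": round_half_up(result.ci_high, decimals)
        if result.ci_high != float("inf") else None,
        "chi2": round_half_up(result.chi2, 3),
        "p": round_half_up(result.p, 3),
        "method": result.method,
    }


def _format_text(report: dict) -> str:
    c = report["cascade"]
    lines = [
        f"Screened patients: {c['n_total']}",
        f"Abnormal IHC and/or MSI (MMR-deficient): {c['n_mmr_deficient']} "
        f"({c['pct_mmr_deficient']}%)",
        f"IHC/MSI concordance: {c['n_concordant']}/{c['n_total']} "
        f"({c['pct_concordant']}%); discordant: {c['n_discordant']}",
        f"Loss of MLH1 expression: {c['n_mlh1_loss']} ({c['pct_mlh1_loss']}%)",
    ]
    if "pct_mlh1_methylated_of_loss" in c:
        lines.append(
            f"MLH1 promoter methylated (tumor): {c['n_mlh1_methylated']}/"
            f"{c['n_mlh1_loss']} ({c['pct_mlh1_methylated_of_loss']}%)"
        )
    lines.append(
        f"Suspected Lynch syndrome: {c['n_suspected']} ({c['pct_suspected']}%)"
    )
    if c["n_tested"]:
        lines.append(
            f"Germline tested: {c['n_tested']}; pathogenic mutation: "
            f"{c['n_pathogenic']} ({c.get('pct_pathogenic_of_tested')}% of tested)"
        )
        lines.append(
            f"Observed prevalence: {c['prevalence_observed_pct']}%; "
            f"predictive frequency: {c.get('predictive_frequency_pct')}%"
        )
    else:
        lines.append(f"Observed prevalence: {c['prevalence_observed_pct']}%")
    for assoc in report.get("associations", {}).values():
        orr = assoc["odds_ratio"]
        lines.append(
            f"{assoc['variable']}: OR {orr} "
            f"({assoc['ci_low']}-{assoc['ci_high']}), p={assoc['p']} "
            f"[{assoc['method']}]"
        )
    return "\n".join(lines) + "\n"


def write_report(report: dict, path: str | Path,
                 format: Literal["json", "text"] = "json") -> None:
    """Write the report as schema-stable JSON or human-readable text."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    elif format == "text":
        path.write_text(_format_text(report))
    else:
        raise ValueError(f"unknown report format {format!r}")
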