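"""Delimited-text and JSON/YAML interchange.

All tabular data moves as plain CSV through pandas; acquisition
parameters and calibration models are serialized as JSON (YAML also
accepted for configs).  Schemas:

ROI signal table (one row per ROI)
    subject_id, roi_id, region, layer, area, si_ip, si_op
    [, te_1..te_k, sig_1..sig_k]   (optional multi-echo series)

Phantom table (one row per phantom ROI)
    vial_id, actual_ff_percent, nominal_ff_percent, layer, roi_id,
    area, si_ip, si_op [, te_*/sig_*]

Subject profile table (one row per subject)
    subject_id, age, group, abstinence, ff_caput, ff_corpus, ff_cauda,
    ff_whole, delta_ff
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .calibration import PhantomVial
from .roi import RoiMeasurement, SubjectPancreasProfile
from .signal_model import AcquisitionParams, EchoPair, EchoSeries

__all__ = [
    "SchemaError",
    "rois_to_frame",
    "frame_to_rois",
    "phantom_to_frame",
    "frame_to_phantom",
    "profiles_to_frame",
    "frame_to_profiles",
    "load_acquisition_params",
    "save_acquisition_params",
]

ROI_REQUIRED = ("subject_id", "roi_id", "region", "layer", "si_ip", "si_op")
PHANTOM_REQUIRED = ("vial_id", "actual_ff_percent", "layer", "roi_id",
                    "si_ip", "si_op")
PROFILE_COLUMNS = ("subject_id", "age", "group", "abstinence", "ff_caput",
                   "ff_corpus", "ff_cauda", "ff_whole", "delta_ff")


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


def _check_columns(df: pd.DataFrame, required: Iterable[str],
                   what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )


def _series_columns(df: pd.DataFrame) -> list[tuple[str, str]]:
    pairs = []
    k = 1
    while f"te_{k}" in df.columns and f"sig_{k}" in df.columns:
        pairs.append((f"te_{k}", f"sig_{k}"))
        k += 1
    return pairs


def _roi_row(roi: RoiMeasurement) -> dict:
    row: dict[str, object] = {
        "roi_id": roi.roi_id, "region": roi.region, "layer": roi.layer,
        "area": roi.area,
        "si_ip": roi.pair.si_ip if roi.pair else float("nan"),
        "si_op": roi.pair.si_op if roi.pair else float("nan"),
    }
    if roi.series is not None:
        for k, (te, sig) in enumerate(zip(roi.series.tes,
                                          roi.series.signals), start=1):
            row[f"te_{k}"] = te
            row[f"sig_{k}"] = sig
    return row


def _row_roi(row: pd.Series, pairs: list[tuple[str, str]]) -> RoiMeasurement:
    series = None
    if pairs:
        tes, sigs = [], []
        for te_c, sig_c in pairs:
            if pd.notna(row[te_c]) and pd.notna(row[sig_c]):
                tes.append(float(row[te_c]))
                sigs.append(float(row[sig_c]))
        if tes:
            series = EchoSeries(tes=tuple(tes), signals=tuple(sigs))
    area = float(row["area"]) if "area" in row and pd.notna(row["area"]) \
        else None
    return RoiMeasurement(
        roi_id=str(row["roi_id"]), region=str(row["region"]),
        layer=int(row["layer"]), area=area,
        pair=EchoPair(float(row["si_ip"]), float(row["si_op"])),
        series=series,
    )


def rois_to_frame(rois_by_subject: Mapping[str, Iterable[RoiMeasurement]]
                  ) -> pd.DataFrame:
    """ROI measurements of one or more subjects as a flat table."""
    rows = []
    for subject_id, rois in rois_by_subject.items():
        for roi in rois:
            rows.append({"subject_id": subject_id, **_roi_row(roi)})
    return pd.DataFrame(rows)


def frame_to_rois(df: pd.DataFrame) -> dict[str, list[RoiMeasurement]]:
    """Parse an ROI signal table, grouped by subject.

    Raises :class:`SchemaError` naming the offending column or the
    1-based row number of an invalid record.
    """
    _check_columns(df, ROI_REQUIRED, "ROI table")
    pairs = _series_columns(df)
    out: dict[str, list[RoiMeasurement]] = {}
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            roi = _row_roi(row, pairs)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"ROI table row {i}: {exc}") from exc
        out.setdefault(str(row["subject_id"]), []).append(roi)
    return out


def phantom_to_frame(vials: Iterable[PhantomVial]) -> pd.DataFrame:
    rows = []
    for vial in vials:
        for roi in vial.roi_measurements:
            rows.append({
                "vial_id": vial.vial_id,
                "actual_ff_percent": vial.actual_ff,
                "nominal_ff_percent": vial.nominal_ff,
                **_roi_row(roi),
            })
    return pd.DataFrame(rows)


def frame_to_phantom(df: pd.DataFrame) -> list[PhantomVial]:
    _check_columns(df, PHANTOM_REQUIRED, "phantom table")
    pairs = _series_columns(df)
    vials: dict[str, PhantomVial] = {}
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        vid = str(row["vial_id"])
        if vid not in vials:
            nominal = (float(row["nominal_ff_percent"])
                       if "nominal_ff_percent" in row
                       and pd.notna(row["nominal_ff_percent"]) else None)
            vials[vid] = PhantomVial(
                vial_id=vid, actual_ff=float(row["actual_ff_percent"]),
                nominal_ff=nominal)
        try:
            vials[vid].roi_measurements.append(_row_roi(row, pairs))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"phantom table row {i}: {exc}") from exc
    return list(vials.values())


def profiles_to_frame(profiles: Iterable[SubjectPancreasProfile]
                      ) -> pd.DataFrame:
    rows = [{
        "subject_id": p.subject_id, "age": p.age, "group": p.group,
        "abstinence": p.abstinence, "ff_caput": p.ff_caput,
        "ff_corpus": p.ff_corpus, "ff_cauda": p.ff_cauda,
        "ff_whole": p.ff_whole, "delta_ff": p.delta_ff,
    } for p in profiles]
    return pd.DataFrame(rows, columns=list(PROFILE_COLUMNS))


def frame_to_profiles(df: pd.DataFrame) -> list[SubjectPancreasProfile]:
    _check_columns(df, PROFILE_COLUMNS[:7], "profile table")
    profiles = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            profiles.append(SubjectPancreasProfile(
                subject_id=str(row["subject_id"]), age=float(row["age"]),
                group=str(row["group"]), abstinence=str(row["abstinence"]),
                ff_caput=float(row["ff_caput"]),
                ff_corpus=float(row["ff_corpus"]),
                ff_cauda=float(row["ff_cauda"])))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"profile table row {i}: {exc}") from exc
    return profiles


def save_acquisition_params(params: AcquisitionParams, path) -> None:
    path = Path(path)
    payload = asdict(params)
    payload["multi_echo_tes"] = list(payload["multi_echo_tes"])
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2) + "\n")


def load_acquisition_params(path) -> AcquisitionParams:
    """Read acquisition parameters from a JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    payload = (yaml.safe_load(text) if path.suffix in (".yaml", ".yml")
               else json.loads(text))
    payload["multi_echo_tes"] = tuple(payload.get(
        "multi_echo_tes", AcquisitionParams().multi_echo_tes))
    return AcquisitionParams(**payload)
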