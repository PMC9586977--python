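"""Readers and writers for the tabular experiment formats.

ITC titrations arrive as a CSV of per-injection heats plus a YAML
protocol header (concentrations, cell volume, temperature); MALS traces
as a long-format CSV of (time, concentration, angle, Rθ).  Fold-call
and geometry tables are written as CSV/JSON by the callers.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .biophys import (
    BindingFit,
    BiophysicsError,
    ITCExperiment,
    ITCProtocol,
    MALSSlice,
)

__all__ = [
    "read_itc_protocol",
    "read_itc_csv",
    "write_itc_csv",
    "binding_fit_to_json",
    "read_mals_csv",
    "write_mals_csv",
    "write_fasta",
]


def read_itc_protocol(path: str | Path) -> ITCProtocol:
    """Load a titration protocol from YAML.

    Keys: ``cell_conc_M``, ``syringe_conc_M``, ``cell_volume_L``,
    ``temperature_K`` and either ``injection_volume_L`` +
    ``n_injections`` or an explicit ``injection_volumes_L`` list.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise BiophysicsError(f"protocol file {path} is not a YAML mapping")
    if "injection_volumes_L" in cfg:
        vols = tuple(float(v) for v in cfg["injection_volumes_L"])
    else:
        vols = (float(cfg["injection_volume_L"]),) * int(cfg["n_injections"])
    return ITCProtocol(
        cell_conc=float(cfg["cell_conc_M"]),
        syringe_conc=float(cfg["syringe_conc_M"]),
        cell_volume=float(cfg["cell_volume_L"]),
        injection_volumes=vols,
        temperature=float(cfg.get("temperature_K", 277.15)),
    )


def read_itc_csv(data_path: str | Path, protocol_path: str | Path) -> ITCExperiment:
    """Assemble an experiment from a heats CSV and a protocol YAML.

    The CSV needs columns ``injection``, ``volume_uL``, ``heat_ucal``;
    injection volumes in the CSV override the protocol's when present.
    """
    df = pd.read_csv(data_path).sort_values("injection")
    protocol = read_itc_protocol(protocol_path)
    if "volume_uL" in df.columns:
        vols = tuple(float(v) * 1e-6 for v in df["volume_uL"])
        protocol = ITCProtocol(
            cell_conc=protocol.cell_conc,
            syringe_conc=protocol.syringe_conc,
            cell_volume=protocol.cell_volume,
            injection_volumes=vols,
            temperature=protocol.temperature,
        )
    return ITCExperiment(
        protocol=protocol, heats=tuple(float(q) for q in df["heat_ucal"])
    )


def write_itc_csv(experiment: ITCExperiment, data_path: str | Path,
                  protocol_path: Optional[str | Path] = None) -> None:
    p = experiment.protocol
    pd.DataFrame(
        {
            "injection": range(1, len(experiment.heats) + 1),
            "volume_uL": [v * 1e6 for v in p.injection_volumes],
            "heat_ucal": experiment.heats,
        }
    ).to_csv(data_path, index=False)
    if protocol_path is not None:
        Path(protocol_path).write_text(
            yaml.safe_dump(
                {
                    "cell_conc_M": p.cell_conc,
                    "syringe_conc_M": p.syringe_conc,
                    "cell_volume_L": p.cell_volume,
                    "injection_volume_L": p.injection_volumes[0],
                    "n_injections": len(p.injection_volumes),
                    "temperature_K": p.temperature,
                },
                sort_keys=True,
            )
        )


def binding_fit_to_json(fit: BindingFit) -> str:
    d = asdict(fit)
    d["k_d_uM"] = fit.k_d * 1e6
    return json.dumps(d, indent=2, sort_keys=True)


def read_mals_csv(path: str | Path, k_optical: Optional[float] = None) -> list[MALSSlice]:
    """Read a long-format MALS trace CSV into per-time slices.

    Columns: ``time``, ``concentration``, ``angle``, ``r_theta`` and
    optionally ``k_optical`` (constant per file; else pass it
    explicitly).
    """
    df = pd.read_csv(path)
    if k_optical is None:
        if "k_optical" not in df.columns:
            raise BiophysicsError(
                "k_optical must be a CSV column or passed explicitly"
            )
        k_vals = df["k_optical"].unique()
        if len(k_vals) != 1:
            raise BiophysicsError("k_optical must be constant across the file")
        k_optical = float(k_vals[0])
    slices = []
    for t, grp in df.groupby("time", sort=True):
        conc = grp["concentration"].unique()
        if len(conc) != 1:
            raise BiophysicsError(f"inconsistent concentration at time {t}")
        slices.append(
            MALSSlice(
                time=float(t),
                concentration=float(conc[0]),
                angles=tuple(float(a) for a in grp["angle"]),
                r_theta=tuple(float(r) for r in grp["r_theta"]),
                k_optical=k_optical,
            )
        )
    return slices


def write_mals_csv(slices: list[MALSSlice], path: str | Path) -> None:
    rows = []
    for s in slices:
        for a, r in zip(s.angles, s.r_theta):
            rows.append(
                {
                    "time": s.time,
                    "concentration": s.concentration,
                    "angle": a,
                    "r_theta": r,
                    "k_optical": s.k_optical,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
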