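"""File I/O and pipeline configuration.

Spectra travel as two-column CSV (``field_mT,intensity``, header row, UTF-8)
with an optional ``<name>.meta.yaml`` sidecar carrying acquisition metadata
(microwave frequency, temperature, protein/ligand identities and
concentrations).  A minimal JCAMP-DX reader handles the common
``(X++(Y..Y))`` tabular dialect exported by EPR spectrometers; on parse
failure the CSV path is tried with a logged warning.  FASTA reading goes
through Biopython.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .errors import ConfigError, FieldOrderWarning, ParseError
from .forward import SpectrumTrace
from .hydropathy import SequenceRecord

__all__ = ["read_spectrum_csv", "write_spectrum_csv", "read_spectrum",
           "read_jcampdx", "read_fasta", "packaged_fasta_path",
           "PipelineConfig", "load_config", "parse_temperature", "config_hash"]

log = logging.getLogger("spinbind")


def parse_temperature(value) -> float:
    """Kelvin from a number (K) or a string with an explicit '<x>C' suffix."""
    if isinstance(value, str):
        v = value.strip()
        if v.endswith(("C", "c")):
            return float(v[:-1]) + 273.15
        if v.endswith(("K", "k")):
            return float(v[:-1])
        return float(v)
    return float(value)


def read_spectrum_csv(path: str | Path) -> SpectrumTrace:
    """Read a two-column spectrum CSV; auto-sorts a descending axis."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    cols = [c.strip() for c in df.columns]
    if len(cols) < 2:
        raise ParseError(f"{path}: expected two columns, found {cols}")
    df.columns = cols
    fcol = "field_mT" if "field_mT" in cols else cols[0]
    icol = "intensity" if "intensity" in cols else cols[1]
    for col in (fcol, icol):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(f"{path}: non-numeric value in column "
                             f"{col!r} at line {line}")
    field = pd.to_numeric(df[fcol]).to_numpy(float)
    inten = pd.to_numeric(df[icol]).to_numpy(float)
    if np.any(np.diff(field) <= 0):
        warnings.warn(FieldOrderWarning(
            f"{path.name}: field axis not strictly increasing; sorting"))
        order = np.argsort(field)
        field, inten = field[order], inten[order]

    meta, mw, temp = {}, 9.47, 310.15
    sidecar = path.with_suffix(".meta.yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        mw = float(meta.pop("mw_freq_GHz", mw))
        temp = parse_temperature(meta.pop("temperature", temp))
    return SpectrumTrace(field_mT=field, intensity=inten, mw_freq_GHz=mw,
                         temperature_K=temp, meta=meta)


def write_spectrum_csv(trace: SpectrumTrace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"field_mT": trace.field_mT,
                  "intensity": trace.intensity}).to_csv(path, index=False)
    side = {"mw_freq_GHz": trace.mw_freq_GHz,
            "temperature": trace.temperature_K, **trace.meta}
    path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(side))


def read_jcampdx(path: str | Path) -> SpectrumTrace:
    """Minimal JCAMP-DX reader for the (X++(Y..Y)) tabular dialect."""
    path = Path(path)
    labels, ydata = {}, []
    in_table = False
    for ln, raw in enumerate(path.read_text(errors="replace").splitlines(), 1):
        line = raw.strip()
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            in_table = key == "XYDATA"
            labels[key] = val.strip()
            continue
        if in_table and line:
            try:
                nums = [float(tok) for tok in line.replace(",", " ").split()]
            except ValueError as exc:
                raise ParseError(f"{path}: bad XYDATA at line {ln}") from exc
            ydata.extend(nums[1:])  # first token is the X of the row
    try:
        first = float(labels["FIRSTX"])
        last = float(labels["LASTX"])
        npts = int(float(labels["NPOINTS"]))
        yfac = float(labels.get("YFACTOR", 1.0))
    except KeyError as exc:
        raise ParseError(f"{path}: missing JCAMP header {exc}") from exc
    if len(ydata) != npts:
        raise ParseError(f"{path}: NPOINTS={npts} but {len(ydata)} Y values")
    field = np.linspace(first, last, npts)
    if labels.get("XUNITS", "").upper().startswith("GAUSS"):
        field = field / 10.0  # Gauss -> mT
    inten = np.asarray(ydata) * yfac
    if field[0] > field[-1]:
        field, inten = field[::-1], inten[::-1]
    return SpectrumTrace(field_mT=field, intensity=inten,
                         mw_freq_GHz=float(labels.get(".MWFREQUENCY", 9.47)),
                         meta={"source": "jcamp-dx"})


def read_spectrum(path: str | Path) -> SpectrumTrace:
    """Dispatch by extension; JCAMP-DX failures fall back to CSV parsing."""
    path = Path(path)
    if path.suffix.lower() in (".dx", ".jdx"):
        try:
            return read_jcampdx(path)
        except ParseError as exc:
            log.warning("JCAMP-DX parse failed (%s); trying CSV", exc)
    return read_spectrum_csv(path)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Multi-record FASTA -> validated :class:`SequenceRecord` list."""
    path = Path(path)
    records = [SequenceRecord(id=rec.id, residues=str(rec.seq))
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def packaged_fasta_path() -> Path:
    """Path of the packaged canonical FABP3/4/5 sequence fixture."""
    return Path(__file__).parent / "data" / "fabp_sequences.fasta"


# ---------------------------------------------------------------------------
# pipeline configuration

_DEFAULT_CONFIG = {
    "paths": {"spectra_dir": "spectra", "components": None, "output_dir": "out"},
    "analysis": {
        "engine": "auto",
        "refine": "none",
        "field_start_mT": 332.5,
        "field_stop_mT": 342.5,
        "field_points": 4096,
        "mw_freq_GHz": 9.47,
        "c_ligand_uM": 20.0,
        "release_free_rise": 0.15,
        "destroy_free_rise": 0.10,
        "release_integral_keep": 0.70,
        "destroy_integral_drop": 0.50,
    },
    "thermo": {"T_epr": 310.15, "T_mst": 295.15},
    "synth": {"preset": "fabp3_like", "noise_snr": 50.0},
    "seed": 0,
    "log_level": "INFO",
}


@dataclasses.dataclass
class PipelineConfig:
    paths: dict
    analysis: dict
    thermo: dict
    synth: dict
    seed: int = 0
    log_level: str = "INFO"

    @property
    def t_epr_K(self) -> float:
        return parse_temperature(self.thermo["T_epr"])

    @property
    def t_mst_K(self) -> float:
        return parse_temperature(self.thermo["T_mst"])


def _merge(defaults: dict, user: dict, path="") -> dict:
    out = dict(defaults)
    for key, val in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge(defaults[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    user = {}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: config root must be a mapping")
    merged = _merge(_DEFAULT_CONFIG, user)
    return PipelineConfig(**merged)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
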