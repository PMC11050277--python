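"""Configuration files, delimited exports, and figure rendering."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from .cable_propagation import VoltageField
from .params import (
    CableParams,
    ClusterSpec,
    MembraneParams,
    MgBlockParams,
    ModelParams,
    ParameterError,
    ProtocolSpec,
    ReceptorParams,
    AMPA_DEFAULT,
    NMDA_DEFAULT,
)

log = logging.getLogger("dendramp")

__all__ = ["RunConfig", "load_config", "apply_overrides", "export_field",
           "export_trace", "render"]

_SECTIONS = {
    "membrane": MembraneParams,
    "cable": CableParams,
    "mg": MgBlockParams,
    "ampa": ReceptorParams,
    "nmda": ReceptorParams,
    "cluster": ClusterSpec,
}
_TOP_KEYS = set(_SECTIONS) | {"protocol", "duration", "out_dir", "render"}


@dataclasses.dataclass
class RunConfig:
    """Resolved run configuration: protocol name plus parameter overrides."""

    protocol: str = "fig1c"
    duration: Optional[float] = None
    overrides: Dict[str, Dict] = dataclasses.field(default_factory=dict)
    out_dir: str = "out"
    render: bool = False

    def build_params(self) -> ModelParams:
        base = ModelParams()
        kw = {}
        for section, cls in _SECTIONS.items():
            if section == "cluster":
                continue
            ov = self.overrides.get(section)
            if ov:
                default = {
                    "ampa": AMPA_DEFAULT, "nmda": NMDA_DEFAULT,
                }.get(section) or getattr(base, section)
                kw[section] = dataclasses.replace(default, **ov)
        return dataclasses.replace(base, **kw)

    def build_protocol(self, base: ProtocolSpec) -> ProtocolSpec:
        spec = base
        params = self.build_params()
        spec = dataclasses.replace(spec, params=params)
        if self.duration is not None:
            spec = dataclasses.replace(spec, duration=self.duration)
        clu_ov = self.overrides.get("cluster")
        if clu_ov:
            if spec.cluster is None:
                spec = dataclasses.replace(spec, cluster=ClusterSpec(**clu_ov))
            else:
                spec = dataclasses.replace(
                    spec, cluster=dataclasses.replace(spec.cluster, **clu_ov))
        # rebuild synaptic inputs with overridden receptor defaults
        if "ampa" in self.overrides or "nmda" in self.overrides:
            ampa = dataclasses.replace(AMPA_DEFAULT,
                                       **self.overrides.get("ampa", {}))
            nmda = dataclasses.replace(NMDA_DEFAULT,
                                       **self.overrides.get("nmda", {}))
            inputs = tuple(dataclasses.replace(s, ampa=ampa, nmda=nmda)
                           for s in spec.inputs)
            spec = dataclasses.replace(spec, inputs=inputs)
        return spec


def _check_section(section: str, values: Dict) -> Dict:
    cls = _SECTIONS[section]
    known = {f.name for f in dataclasses.fields(cls)}
    for key in values:
        if key not in known:
            raise ParameterError(
                f"unknown key '{section}.{key}'; known keys: "
                f"{', '.join(sorted(known))}"
            )
    # instantiating validates the invariants right away
    defaults = {"ampa": AMPA_DEFAULT, "nmda": NMDA_DEFAULT}.get(section)
    if defaults is not None:
        dataclasses.replace(defaults, **values)
    else:
        cls(**{**values})
    return dict(values)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML config; unset keys fall back to the model defaults."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ParameterError(f"malformed config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ParameterError(f"config {path} must be a mapping")
    cfg = RunConfig()
    for key, value in data.items():
        if key not in _TOP_KEYS:
            raise ParameterError(
                f"unknown config key '{key}'; known: {', '.join(sorted(_TOP_KEYS))}"
            )
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ParameterError(f"section '{key}' must be a mapping")
            cfg.overrides[key] = _check_section(key, value)
        elif key == "protocol":
            cfg.protocol = str(value)
        elif key == "duration":
            cfg.duration = float(value)
        elif key == "out_dir":
            cfg.out_dir = str(value)
        elif key == "render":
            cfg.render = bool(value)
    return cfg


def apply_overrides(cfg: RunConfig, pairs: Sequence[str]) -> RunConfig:
    """Apply flat ``section.key=value`` overrides on top of a config."""
    for pair in pairs:
        if "=" not in pair or "." not in pair.split("=", 1)[0]:
            raise ParameterError(
                f"override '{pair}' must look like section.key=value"
            )
        dotted, raw = pair.split("=", 1)
        section, key = dotted.split(".", 1)
        if section not in _SECTIONS:
            raise ParameterError(
                f"unknown override section '{section}'; known: "
                f"{', '.join(sorted(_SECTIONS))}"
            )
        try:
            value = yaml.safe_load(raw)
        except yaml.YAMLError:
            value = raw
        merged = {**cfg.overrides.get(section, {}), key: value}
        cfg.overrides[section] = _check_section(section, merged)
    return cfg


def export_field(field: VoltageField, path: str | Path) -> Path:
    """Write the field as CSV: first row times (ms), first column x (um).

    A comment line documents the axis convention; round-tripping through
    :func:`numpy.loadtxt` reproduces the values to better than 1e-6 mV.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# rows: position um (x=0 synaptic end); "
                 "columns: time ms; cells: membrane potential mV\n")
        fh.write("x_um|t_ms," + ",".join(f"{t:.6g}" for t in field.times) + "\n")
        for x, row in zip(field.positions, field.values):
            fh.write(f"{x:.6g}," + ",".join(f"{v:.9g}" for v in row) + "\n")
    return path


def import_field(path: str | Path, v_rest: float = -65.0) -> VoltageField:
    """Read back a field written by :func:`export_field`."""
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln and not ln.startswith("#")]
    times = np.array([float(v) for v in lines[0].split(",")[1:]])
    positions, rows = [], []
    for ln in lines[1:]:
        parts = ln.split(",")
        positions.append(float(parts[0]))
        rows.append([float(v) for v in parts[1:]])
    return VoltageField(positions=np.array(positions), times=times,
                        values=np.array(rows), v_rest=v_rest)


def export_trace(times: np.ndarray, trace: np.ndarray, path: str | Path,
                 label: str = "v_mV") -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"t_ms,{label}\n")
        for t, v in zip(times, trace):
            fh.write(f"{t:.6g},{v:.9g}\n")
    return path


def render(field: VoltageField, traces: Optional[List[tuple]] = None,
           path: str | Path = "field.png") -> Optional[Path]:
    """Render the field heatmap with optional labeled far-edge traces.

    Purely presentational; failures are logged and never fatal.
    """
    path = Path(path)
    try:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        n_rows = 2 if traces else 1
        fig, axes = plt.subplots(n_rows, 1, figsize=(8, 4 * n_rows),
                                 squeeze=False)
        ax = axes[0][0]
        mesh = ax.pcolormesh(field.times, field.positions, field.values,
                             cmap="hsv", shading="auto")
        fig.colorbar(mesh, ax=ax, label="Vm (mV)")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("position (um)")
        ax.set_title("membrane potential along the dendrite")
        if traces:
            ax2 = axes[1][0]
            for label, t, v in traces:
                ax2.plot(t, v, label=str(label))
            ax2.set_xlabel("time (ms)")
            ax2.set_ylabel("Vm (mV)")
            ax2.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)
        return path
    except Exception:                           # pragma: no cover
        log.exception("rendering failed; data exports are unaffected")
        return None


def summary_json(summaries: Dict[str, Dict], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summaries, indent=2, default=float) + "\n")
    return path
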