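"""Run configuration, regime presets and the seeded pipeline.

A single global seed fans out to per-stage seeds through a named substream
registry (geometry / connectome / dynamics / optimiser), so e.g. the
geometry can be held fixed while dynamics seeds vary.  Every value that is
not printed in the source model description carries a ``provenance`` tag:
``"inherited"`` (taken from the predecessor MSN/FS models) or ``"chosen"``
(this package's own default); printed values are tagged ``"printed"``.

Configs are plain nested dicts, readable from a TOML file; the full config
is echoed verbatim (JSON) into every artefact directory.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .connectome import build_network
from .dynamics import DBSParams, ModelParams, simulate
from .geometry import generate_synthetic_striatum
from .observables import band_fraction, mean_activity, power_spectrum, sync_index

__all__ = ["RunConfig", "PHI_OPTIMA", "preset", "substream_seed", "run_pipeline", "load_config"]


# printed Phi-optimal DBS vectors (Results section values)
PHI_OPTIMA = {
    "dbs_phi1": (-11.39, 4.21, 15.11, 195.02, 99.73),
    "dbs_phi2": (-15.23, 3.37, 34.30, 253.74, 64.02),
    "dbs_phi3": (-6.46, 4.87, -0.75, 367.89, 109.19),
}

PROVENANCE = {
    "drive.I0": "printed",
    "syn.alpha": "printed",
    "syn.beta_msn": "printed",
    "syn.beta_fs": "printed",
    "syn.E_GABA": "printed",
    "msn.*": "inherited",
    "fs.*": "inherited",
    "syn.g_MM": "chosen",
    "syn.g_FM": "chosen",
    "syn.g_FF": "chosen",
    "syn.g_MF": "chosen",
    "dbs.delta": "chosen",
    "dbs.sigma": "chosen",
}


@dataclass
class RunConfig:
    name: str = "custom"
    seed: int = 0
    n_total: int = 1995
    fs_fraction: float = 0.05
    k_msn: int = 20
    k_fs: int = 100
    radius: float = 5.0
    p_remote: float = 0.05
    t_end: float = 1000.0
    dt: float = 0.05
    params: ModelParams = field(default_factory=ModelParams)
    dbs: DBSParams | None = None
    provenance: dict = field(default_factory=lambda: dict(PROVENANCE))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def substream_seed(global_seed: int, stream: str) -> int:
    """Deterministic named substream of the global seed (< 2**31)."""
    import zlib

    ss = np.random.SeedSequence([global_seed, zlib.crc32(stream.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def preset(name: str, seed: int = 0) -> RunConfig:
    """Regime presets: healthy (I0=5), abnormal (I0=1.5), and the three
    DBS presets applying the printed Phi-optimal parameter vectors on top
    of the abnormal state."""
    base = RunConfig(name=name, seed=seed)
    if name == "healthy":
        return replace(base, params=base.params.with_drive(5.0))
    if name == "abnormal":
        return replace(base, params=base.params.with_drive(1.5))
    if name in PHI_OPTIMA:
        x0, y0, z0, amp, freq = PHI_OPTIMA[name]
        return replace(
            base,
            params=base.params.with_drive(1.5),
            dbs=DBSParams(x0=x0, y0=y0, z0=z0, amplitude=amp, frequency=freq),
        )
    raise ValueError(f"unknown preset {name!r}")


def load_config(path) -> RunConfig:
    """Read a TOML run configuration; unknown keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = preset(raw.pop("preset", "healthy"), seed=raw.pop("seed", 0))
    dbs_raw = raw.pop("dbs", None)
    params_raw = raw.pop("params", {})
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)!r}")
    cfg = replace(cfg, **raw)
    if dbs_raw is not None:
        cfg = replace(cfg, dbs=DBSParams(**dbs_raw))
    if params_raw:
        drive = params_raw.get("drive", {})
        if drive:
            cfg = replace(cfg, params=cfg.params.with_drive(drive["I0"]))
    return cfg


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Generate geometry, build the network, simulate, and collate the
    biomarker report; artefacts are written under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(_jsonable(cfg.to_dict()), indent=1, sort_keys=True))

    table = generate_synthetic_striatum(
        cfg.n_total, cfg.fs_fraction, seed=substream_seed(cfg.seed, "geometry")
    )
    net = build_network(
        table,
        k_msn=cfg.k_msn,
        k_fs=cfg.k_fs,
        radius=cfg.radius,
        p_remote=cfg.p_remote,
        seed=substream_seed(cfg.seed, "connectome"),
    )
    res = simulate(
        net,
        cfg.params,
        dbs=cfg.dbs,
        t_end=cfg.t_end,
        dt=cfg.dt,
        seed=substream_seed(cfg.seed, "dynamics"),
    )

    act = mean_activity(res.spikes, net.n, cfg.t_end)
    # spectra are computed after a 200 ms settling window (initial-condition
    # transient), or from the start for runs shorter than 400 ms
    cut = int(round(200.0 / cfg.dt)) if cfg.t_end >= 400.0 else 0
    spec = power_spectrum(res.mean_V[cut:], cfg.dt, smooth_width=2.0)
    report = {
        "preset": cfg.name,
        "seed": cfg.seed,
        "n_neurons": net.n,
        "mean_rate_hz": act.time_mean(),
        "spectral_peak_hz": spec.peak_frequency(f_min=1.0),
        "gamma_band_fraction": band_fraction(spec),
    }
    try:
        report["r_sync_max"] = sync_index(res.spikes, res.t[:: max(1, int(1.0 / cfg.dt))]).r_max
    except ValueError:
        report["r_sync_max"] = None

    rows = [(i, t) for i, st in enumerate(res.spikes) for t in st]
    with open(out / "spikes.csv", "w") as fh:
        fh.write("neuron_id,t_ms\n")
        fh.writelines(f"{i},{t:.3f}\n" for i, t in rows)
    with open(out / "activity.csv", "w") as fh:
        fh.write("t_ms,rate_hz\n")
        fh.writelines(f"{t:.1f},{r:.6f}\n" for t, r in zip(act.t, act.rate))
    (out / "biomarkers.json").write_text(json.dumps(_jsonable(report), indent=1, sort_keys=True))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
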