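"""Trace files, cohort manifests, run configuration and the pipeline driver.

Trace files are plain CSV with header ``time_s,extension_nm,force_pN``
and ``#``-prefixed ``key: value`` metadata lines, one row per sample.
Ground truth travels in a JSON sidecar next to each synthetic trace.
Cohort manifests and run configurations are YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binding, exchange
from .calibration import OverstretchCalibrator
from .segmentation import GreedySegmenter, SegmentationParams
from .simulate import GroundTruth, Trace, simulate_cohort

__all__ = [
    "read_trace",
    "write_trace",
    "read_ground_truth",
    "write_ground_truth",
    "CohortManifest",
    "ManifestEntry",
    "RunConfig",
    "run_pipeline",
    "demo_config",
]

TRACE_COLUMNS = ("time_s", "extension_nm", "force_pN")


# ---------------------------------------------------------------------------
# trace files


def write_trace(trace: Trace, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"# {k}: {json.dumps(v)}" for k, v in sorted(trace.meta.items())]
    lines.append(f"# construct_bp: {trace.construct_bp}")
    header = "\n".join(lines)
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "extension_nm": trace.extension,
            "force_pN": trace.force,
        }
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False, float_format="%.6f")
    return path


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    meta: dict = {}
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                try:
                    meta[k.strip()] = json.loads(v.strip())
                except json.JSONDecodeError:
                    meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    steps = np.diff(t)
    bad = np.flatnonzero(steps <= 0)
    if len(bad):
        lineno = n_meta + 2 + int(bad[0]) + 1  # header + first offending row
        raise ValueError(f"{path}: non-monotone time at data line {lineno}")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: non-uniform time grid")
    construct_bp = int(meta.pop("construct_bp", 48502))
    return Trace(
        t,
        df["extension_nm"].to_numpy(dtype=float),
        df["force_pN"].to_numpy(dtype=float),
        construct_bp,
        meta,
    )


def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(gt.to_dict(), indent=1, sort_keys=True) + "\n")
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        d["breakpoints"], d["segment_slopes"], d["pause_levels"], d["n_filaments_bound"]
    )


# ---------------------------------------------------------------------------
# manifest and config


@dataclass
class ManifestEntry:
    path: str
    kind: str = "binding"  # binding | exchange | control | ramp
    mode: str = ""
    filament_nt: int = 0
    pulled_strand: str = ""
    force: float = 0.0


@dataclass
class CohortManifest:
    entries: list[ManifestEntry]
    master_seed: int = 0

    def __post_init__(self) -> None:
        paths = [e.path for e in self.entries]
        if len(paths) != len(set(paths)):
            raise ValueError("manifest paths must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortManifest":
        raw = yaml.safe_load(Path(path).read_text())
        entries = [ManifestEntry(**e) for e in raw.get("entries", [])]
        return cls(entries, int(raw.get("master_seed", 0)))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "master_seed": self.master_seed,
            "entries": [asdict(e) for e in self.entries],
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path


_CONFIG_KEYS = {
    "segmentation",
    "noise",
    "measurement_window",
    "seed",
    "cohorts",
    "rate_bootstrap",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration with paper-anchored defaults."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    noise: dict = field(default_factory=dict)
    measurement_window: tuple[float, float] = binding.MEASUREMENT_WINDOW
    seed: int = 0
    cohorts: list[dict] = field(default_factory=list)
    rate_bootstrap: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        seg = SegmentationParams(**raw.get("segmentation", {}))
        window = tuple(raw.get("measurement_window", binding.MEASUREMENT_WINDOW))
        return cls(
            segmentation=seg,
            noise=raw.get("noise", {}),
            measurement_window=window,  # type: ignore[arg-type]
            seed=int(raw.get("seed", 0)),
            cohorts=raw.get("cohorts", []),
            rate_bootstrap=int(raw.get("rate_bootstrap", 1000)),
        )

    def digest(self) -> str:
        payload = {
            "segmentation": asdict(self.segmentation),
            "noise": self.noise,
            "measurement_window": list(self.measurement_window),
            "seed": self.seed,
            "cohorts": self.cohorts,
            "rate_bootstrap": self.rate_bootstrap,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def demo_config() -> RunConfig:
    """Small end-to-end demo: binding, controls and both exchange cohorts."""
    return RunConfig.from_dict(
        {
            "seed": 0,
            "cohorts": [
                {"kind": "binding", "mode": "3p5p", "force": 56, "filament_nt": 700, "replicates": 4},
                {"kind": "control", "force": 56, "replicates": 4},
                {"kind": "exchange", "pulled_strand": "outgoing", "rate": 0.21, "replicates": 8},
                {"kind": "exchange", "pulled_strand": "complementary", "rate": 0.12, "replicates": 8},
            ],
            "rate_bootstrap": 200,
        }
    )


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(
    config: RunConfig,
    manifest: CohortManifest | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run simulate/load → segment → summarize → rates on a cohort.

    Traces come either from ``manifest`` (files on disk) or, when the
    config lists ``cohorts``, from the seeded simulator. Returns (and
    optionally writes) a JSON-serializable results bundle stamped with
    the config hash and master seed. All randomness flows from
    ``config.seed``.
    """
    log: list[str] = []
    if manifest is not None and manifest.entries:
        traces = [(read_trace(e.path), None) for e in manifest.entries]
        for (trace, _), e in zip(traces, manifest.entries):
            for key in ("kind", "mode", "pulled_strand"):
                val = getattr(e, key)
                if val:
                    trace.meta.setdefault(key, val)
    elif config.cohorts:
        traces = simulate_cohort({"cohorts": config.cohorts, "noise": config.noise}, config.seed)
    else:
        raise ValueError("nothing to analyze: empty manifest and no cohorts in config")

    segmenter = GreedySegmenter(**asdict(config.segmentation))
    results: dict = {
        "config_digest": config.digest(),
        "master_seed": config.seed,
        "n_traces": len(traces),
        "segments": [],
        "binding_summaries": [],
        "rates": {},
        "calibration": None,
        "log": log,
    }

    binding_summaries = []
    exchange_slopes: dict[str, list[float]] = {}
    for i, (trace, _gt) in enumerate(traces):
        kind = trace.meta.get("kind", "binding")
        if kind == "ramp":
            try:
                cal = OverstretchCalibrator().fit(trace)
                results["calibration"] = asdict(cal.result_)
            except ValueError as err:
                log.append(f"trace {i}: calibration failed: {err}")
            continue
        seg = segmenter.fit(trace).result_
        results["segments"].append({"trace": i, **seg.to_dict()})
        for s0, s1 in seg.skipped:
            log.append(f"trace {i}: skipped high-noise region {s0:.1f}-{s1:.1f} s")
        if not seg.segments:
            log.append(f"trace {i}: dropped (no segments)")
            continue
        if kind in ("binding", "control"):
            try:
                summ = binding.delta_extension(trace, seg, window=config.measurement_window)
                summ.mode = trace.meta.get("mode", "") or (
                    "control" if kind == "control" else ""
                )
                binding_summaries.append(summ)
            except ValueError as err:
                log.append(f"trace {i}: no extension summary: {err}")
        elif kind == "exchange":
            label = trace.meta.get("pulled_strand", "exchange")
            exchange_slopes.setdefault(label, []).append(
                float(exchange.trace_slopes([seg])[0])
            )

    if binding_summaries:
        table = binding.cohort_summary(binding_summaries)
        results["binding_summaries"] = table.to_dict(orient="records")
    for li, (label, slopes) in enumerate(sorted(exchange_slopes.items())):
        rate_seed = np.random.SeedSequence(entropy=config.seed, spawn_key=(9001, li))
        est = exchange.characteristic_rate(
            np.asarray(slopes), n_boot=config.rate_bootstrap, seed=rate_seed
        )
        results["rates"][label] = est.to_dict()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "results.json").write_text(
            json.dumps(results, indent=1, sort_keys=True, default=float) + "\n"
        )
    return results
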