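"""End-to-end orchestration: configuration, stages, and result bundles.

``run_pipeline`` takes a JSON-style configuration naming either input
containers or a synthetic-generation block, runs the full chain
(aMUA -> cumulative d' -> STC -> spread/tips -> rate-level/DR) per run,
and writes a result bundle to the output directory:

* ``stc_<name>.csv`` -- cumulative-d' matrix (levels x channels);
* ``contours_<name>.csv`` -- iso-d' polylines at 1/2/4;
* ``rate_level_<name>.csv`` -- per-level means, SD, normalized rate;
* ``summary.csv`` -- one row per run x reference d' level with spread,
  tips, DR, best site, and censoring flags;
* ``manifest.json`` -- seed, package version, and every resolved
  parameter value.

The bundle is a pure function of (config, seed): per-run generator
seeds are derived deterministically from the pipeline seed, files carry
no timestamps, and floats are serialized at full precision.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amua import DEFAULTS as AMUA_DEFAULTS
from .amua import compute_amua
from .containers import read_container
from .neurometric import cumulative_dprime
from .rate_level import dynamic_range, fit_sigmoid, rate_level_at_bs
from .stc import TonotopicMap, assign_cf, build_stc, measure_spread
from .synthetic import (
    GroundTruth,
    default_cf_map,
    default_protocol,
    default_truth,
    generate_recording,
)

log = logging.getLogger("icspread")

_TOP_KEYS = {"synthetic", "input", "amua", "dprime", "stc", "rate_level", "tonotopy"}


class ConfigError(ValueError):
    """Unknown or inconsistent configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def default_study_config() -> dict:
    """Three-modality synthetic study at the package's study conditions."""
    runs = [{"name": "acoustic_32khz", "modality": "acoustic"}]
    for modality in ("magnetic", "electric"):
        for site in ("base", "apex"):
            runs.append(
                {"name": f"{modality}_{site}", "modality": modality, "site": site}
            )
    return {"synthetic": {"runs": runs}}


def _resolve_run(run: dict, run_seed: int):
    modality = run.get("modality")
    if modality is None:
        raise ConfigError(f"run {run.get('name')!r} lacks a modality")
    site = run.get("site", "base")
    proto_over = dict(run.get("protocol", {}))
    freq = proto_over.pop("frequency_khz", 32.0)
    repeats = proto_over.pop("repeats", 39)
    protocol = default_protocol(modality, frequency_khz=freq, repeats=repeats)
    if proto_over:
        from .containers import StimulusProtocol

        d = protocol.to_dict()
        d.update(proto_over)
        protocol = StimulusProtocol.from_dict(d)
    truth_over = dict(run.get("truth", {}))
    truth_over.setdefault("seed", run_seed)
    truth = default_truth(modality, site=site, **truth_over)
    return truth, protocol, site


def _run_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def _analyze_one(rec, protocol, cfg, name):
    t0 = time.perf_counter()
    amua_cfg = {**AMUA_DEFAULTS, **cfg.get("amua", {})}
    window = tuple(amua_cfg.pop("window_s"))
    try:
        amua = compute_amua(rec, protocol, window_s=window, **amua_cfg)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage amua failed for run {name!r}: {e}") from e
    log.info(
        "amua[%s]: %s -> %s (%.2fs)",
        name, rec.data.shape, amua.values.shape, time.perf_counter() - t0,
    )
    variance = cfg.get("dprime", {}).get("variance", "rms")
    try:
        dp = cumulative_dprime(amua, variance=variance)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage dprime failed for run {name!r}: {e}") from e
    upsample = int(cfg.get("stc", {}).get("upsample", 10))
    try:
        stc = build_stc(dp, upsample=upsample)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage stc failed for run {name!r}: {e}") from e
    return amua, dp, stc


def _rate_level_row(amua, stc, cfg):
    if not stc.has_response:
        return None
    rlf = rate_level_at_bs(amua, stc.best_site)
    rlf = fit_sigmoid(rlf)
    method = cfg.get("rate_level", {}).get("dr_method", "fit")
    dr = dynamic_range(rlf, method=method)
    return rlf, dr


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """Execute the configured analysis and write the result bundle.

    Returns a dict with the summary DataFrame and output paths.
    """
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "synthetic" not in config and "input" not in config:
        raise ConfigError("config needs a 'synthetic' or 'input' block")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # assemble the recordings to analyze
    jobs = []  # (name, modality, site, rec, protocol, truth_or_None)
    if "synthetic" in config:
        runs = config["synthetic"].get("runs")
        if not runs:
            raise ConfigError("synthetic block needs a non-empty 'runs' list")
        seeds = _run_seeds(seed, len(runs))
        for run, rs in zip(runs, seeds):
            truth, protocol, site = _resolve_run(run, rs)
            name = run.get("name", f"{protocol.modality}_{site}")
            t0 = time.perf_counter()
            rec = generate_recording(truth, protocol)
            log.info(
                "simulate[%s]: %s (%.2fs)",
                name, rec.data.shape, time.perf_counter() - t0,
            )
            jobs.append((name, protocol.modality, site, rec, protocol, truth))
    if "input" in config:
        for entry in config["input"].get("containers", []):
            rec = read_container(entry["path"])
            if rec.protocol is None:
                raise ConfigError(f"container {entry['path']} has no protocol")
            name = entry.get("name", Path(entry["path"]).stem)
            jobs.append(
                (name, rec.protocol.modality, entry.get("site", "base"),
                 rec, rec.protocol, None)
            )

    results = {}
    for name, modality, site, rec, protocol, truth in jobs:
        amua, dp, stc = _analyze_one(rec, protocol, config, name)
        results[name] = dict(
            modality=modality, site=site, rec=rec, protocol=protocol,
            truth=truth, amua=amua, dp=dp, stc=stc,
        )

    # tonotopic map: measured from acoustic runs when >= 2 distinct
    # frequencies have a valid best site, else the generator's map
    tmap = None
    tono_cfg = config.get("tonotopy", {}).get("source", "auto")
    acoustic = [
        r for r in results.values()
        if r["modality"] == "acoustic" and r["stc"].has_response
    ]
    if tono_cfg in ("auto", "measured"):
        pairs = {
            r["protocol"].frequency_khz: r["stc"].best_site for r in acoustic
        }
        if len(pairs) >= 2:
            n_ch = next(iter(results.values()))["rec"].n_channels
            tmap = assign_cf(
                list(pairs.values()), list(pairs.keys()), n_channels=n_ch
            )
    if tmap is None:
        for r in results.values():
            if r["truth"] is not None:
                tmap = TonotopicMap.from_cf(
                    r["truth"].cf_khz, source="ground_truth"
                )
                break
    if tmap is None and tono_cfg == "measured":
        raise ConfigError("measured tonotopy requested but unavailable")
    if tmap is None:
        tmap = TonotopicMap.from_cf(default_cf_map(), source="ground_truth")

    # per-run outputs and the pooled summary table
    summary_rows = []
    paths = {}
    for name, r in results.items():
        stc = r["stc"]
        rec = r["rec"]
        stc_df = pd.DataFrame(
            stc.matrix,
            index=pd.Index(stc.levels, name="level_db"),
            columns=[f"ch{c}" for c in range(stc.n_channels)],
        )
        p = out_dir / f"stc_{name}.csv"
        stc_df.to_csv(p)
        paths[f"stc_{name}"] = p

        crows = []
        for lv, polylines in stc.contours.items():
            for si, seg in enumerate(polylines):
                for level, channel in seg:
                    crows.append(
                        dict(d_level=lv, segment=si, level_db=level,
                             channel=channel)
                    )
        p = out_dir / f"contours_{name}.csv"
        pd.DataFrame(
            crows, columns=["d_level", "segment", "level_db", "channel"]
        ).to_csv(p, index=False)
        paths[f"contours_{name}"] = p

        spread = measure_spread(stc, rec.channel_pitch_um, tmap)
        rl = _rate_level_row(r["amua"], stc, config)
        if rl is not None:
            rlf, dr = rl
            rl_df = pd.DataFrame(
                dict(
                    level_native=rlf.levels_native,
                    level_db=rlf.levels_db,
                    mean_rate=rlf.mean_rate,
                    sd_rate=rlf.sd_rate,
                    normalized=rlf.normalized,
                )
            )
            p = out_dir / f"rate_level_{name}.csv"
            rl_df.to_csv(p, index=False)
            paths[f"rate_level_{name}"] = p
        else:
            rlf, dr = None, None

        for at_d, m in (("2", spread.d2), ("4", spread.d4)):
            summary_rows.append(
                dict(
                    experiment=name,
                    modality=r["modality"],
                    site=r["site"],
                    d_level=int(at_d),
                    best_site=spread.best_site,
                    threshold_level_db=spread.threshold_level,
                    bs_cf_khz=spread.bs_cf_khz,
                    level_at_d=None if m is None else m.level,
                    spread_channels=None if m is None else m.spread_channels,
                    spread_um=None if m is None else m.spread_um,
                    spread_octaves=None if m is None else m.octaves,
                    censored=None if m is None else m.censored,
                    n_tips=spread.n_tips,
                    dr_db=dr,
                    saturated=None if rlf is None else rlf.saturated,
                )
            )

    summary = pd.DataFrame(summary_rows)
    p = out_dir / "summary.csv"
    summary.to_csv(p, index=False)
    paths["summary"] = p

    manifest = dict(
        seed=int(seed),
        package="icspread",
        version=__version__,
        config=_jsonable(config),
        amua_defaults=_jsonable(AMUA_DEFAULTS),
        runs={
            name: dict(
                modality=r["modality"],
                site=r["site"],
                protocol=r["protocol"].to_dict(),
                truth=None if r["truth"] is None else r["rec"].metadata.get("truth"),
            )
            for name, r in results.items()
        },
        tonotopy=dict(
            source=tmap.source,
            cf_khz=[float(x) for x in tmap.cf_khz],
            fit=list(tmap.fit),
        ),
    )
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = p

    return dict(summary=summary, paths=paths, results=results, tonotopy=tmap)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [float(x) for x in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
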