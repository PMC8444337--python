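"""Stage implementations behind :func:`cectrack.trajectory_io.run_pipeline`."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, biasing, calibration, cec_core, fixtures, spectra
from .errors import ConfigurationError
from .topology_states import AcidSpec
from .trajectory_io import FrameSeries, read_xyz_trajectory, write_cec_outputs, write_xyz_trajectory

log = logging.getLogger("cectrack")


def _acid_from_config(config: dict) -> AcidSpec | None:
    blk = config.get("acid")
    if not blk:
        return None
    return AcidSpec(
        oxygens=tuple(blk["oxygens"]),
        carbon=blk.get("carbon"),
        label=blk.get("label", "glu"),
    )


def _params_from_config(config: dict):
    blk = config.get("parameters", {})
    functional = blk.get("functional", "BLYP")
    if "file" in blk:
        return cec_core.load_ct_params(blk["file"], functional=functional)
    return cec_core.default_ct_params(functional)


def _charges_from_config(config: dict):
    blk = config.get("charges", {})
    if "file" in blk:
        return cec_core.load_charge_table(blk["file"])
    return cec_core.DEFAULT_CHARGES


def execute(config: dict, stages: list[str], out_prefix=None) -> dict:
    """Run the validated stages in order; returns products per stage."""
    prefix = Path(out_prefix or config.get("out_prefix", "cectrack_out"))
    prefix.parent.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    products: dict = {"seed": seed}
    series: FrameSeries | None = None

    for stage in stages:
        log.info("running stage %s", stage)
        if stage == "fixtures":
            series = _stage_fixtures(config, prefix, seed, products)
        elif stage == "cec":
            series = series or _load_series(config)
            _stage_cec(config, series, prefix, products)
        elif stage == "spectrum":
            _stage_spectrum(config, series, prefix, products)
        elif stage == "xi":
            series = series or _load_series(config)
            _stage_xi(config, series, prefix, products)
        elif stage == "fit":
            _stage_fit(config, prefix, products)
        elif stage == "grid":
            _stage_grid(config, prefix, products)
        elif stage == "metad-demo":
            _stage_metad(config, prefix, seed, products)
    manifest = {
        "tool": "cectrack",
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "config": {k: v for k, v in config.items() if k != "stages"},
        "products": {k: str(v) for k, v in products.items() if k != "seed"},
    }
    mpath = Path(str(prefix) + "_run_manifest.json")
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    products["manifest"] = mpath
    return products


def _load_series(config: dict) -> FrameSeries:
    blk = config.get("input", {})
    traj = blk.get("trajectory")
    if not traj:
        raise ConfigurationError("config lacks input.trajectory")
    if not Path(traj).exists():
        raise ConfigurationError(f"trajectory file {traj} does not exist")
    return read_xyz_trajectory(traj, dt=blk.get("dt_fs"))


def _stage_fixtures(config, prefix, seed, products) -> FrameSeries:
    blk = config.get("fixtures", {})
    kind = blk.get("kind", "shuttle")
    if kind == "ideal-network":
        frame = fixtures.make_ideal_network(
            branching=tuple(blk.get("branching", (3, 2, 2))),
            hbond_len=blk.get("hbond_len", 1.6),
        )
        series = FrameSeries(frames=[frame], dt=blk.get("dt_fs", 0.5))
    elif kind == "zundel-scan":
        series = fixtures.make_zundel_scan(
            r_oo=blk.get("r_oo", 2.6), n_frames=blk.get("n_frames", 11)
        )
    elif kind == "shuttle":
        series = fixtures.make_shuttle_trajectory(
            n_waters_in_wire=blk.get("n_waters", 4),
            hops=blk.get("hops", 2),
            frames_per_hop=blk.get("frames_per_hop", 20),
        )
    elif kind == "oscillating-track":
        track = fixtures.make_oscillating_track(
            freq_cm=blk.get("freq_cm", 1200.0),
            dt_fs=blk.get("dt_fs", 0.5),
            n=blk.get("n", 4096),
            noise=blk.get("noise", 0.0),
            seed=seed,
        )
        path = Path(str(prefix) + "_track.csv")
        pd.DataFrame(track, columns=["x", "y", "z"]).to_csv(
            path, index=False, float_format="%.10g"
        )
        products["fixture_track"] = path
        return None
    else:
        raise ConfigurationError(f"unknown fixture kind {kind!r}")
    path = Path(str(prefix) + "_fixture.xyz")
    write_xyz_trajectory(series, path)
    products["fixture"] = path
    return series


def _stage_cec(config, series, prefix, products):
    blk = config.get("cec", {})
    params = _params_from_config(config)
    charges = _charges_from_config(config)
    acid = _acid_from_config(config)
    results, statesets = [], []
    for frame in series:
        res, states = cec_core.cec_for_frame(
            frame,
            params,
            charges,
            acid=acid,
            max_shell=blk.get("max_shell", 3),
            cutoff=blk.get("cutoff", 2.5),
        )
        results.append(res)
        statesets.append(states)
    paths = write_cec_outputs(series, results, prefix)
    products.update(paths)
    products["_results"] = results
    if blk.get("dump_states"):
        dump = []
        for fr, ss in zip(series, statesets):
            dump.append(
                {
                    "frame": fr.index,
                    "states": [
                        {
                            "id": st.id,
                            "shell": st.shell,
                            "atoms": list(st.species.atoms),
                            "path": [
                                [h.donor_o, h.shared_h, h.acceptor_o] for h in st.path
                            ],
                        }
                        for st in ss
                    ],
                }
            )
        spath = Path(str(prefix) + "_states.json")
        spath.write_text(json.dumps(dump, indent=1) + "\n")
        products["states"] = spath


def _stage_spectrum(config, series, prefix, products):
    blk = config.get("spectrum", {})
    if "track" in blk:
        df = pd.read_csv(blk["track"])
        cols = [c for c in ("cec_x", "cec_y", "cec_z") if c in df.columns] or ["x", "y", "z"]
        track = df[cols].to_numpy()
        dt = blk.get("dt_fs", 0.5)
    elif "_results" in products:
        track = np.array([r.cec for r in products["_results"]])
        dt = series.dt if series is not None else blk.get("dt_fs", 0.5)
    else:
        raise ConfigurationError("spectrum stage needs spectrum.track or a prior cec stage")
    vel = spectra.estimate_velocity(track, dt)
    spec = spectra.ir_spectrum(vel, dt)
    window_cm = max(blk.get("window_cm", 33.0), spec.resolution)
    sm = spectra.smooth_spectrum(spec, window_cm=window_cm)
    path = Path(str(prefix) + "_spectrum.csv")
    pd.DataFrame(
        {
            "frequency_cm": spec.frequencies,
            "intensity": spec.intensities,
            "intensity_smoothed": sm.intensities,
        }
    ).to_csv(path, index=False, float_format="%.10g")
    products["spectrum"] = path


def _stage_xi(config, series, prefix, products):
    blk = config.get("xi", {})
    acid = _acid_from_config(config)
    if acid is None or len(acid.oxygens) < 2:
        raise ConfigurationError("xi stage needs an acid block with two oxygens")
    o1, o2 = acid.oxygens[:2]
    params = _params_from_config(config)
    charges = _charges_from_config(config)
    kappa = blk.get("kappa", 40.0)
    rows = []
    for frame in series:
        res, _ = cec_core.cec_for_frame(frame, params, charges, acid=acid)
        val, _g = biasing.xi_cv(res.cec, frame.positions[o1], frame.positions[o2], kappa)
        rows.append({"frame": frame.index, "time_fs": frame.time, "xi": val})
    path = Path(str(prefix) + "_xi.csv")
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    products["xi"] = path


def _stage_fit(config, prefix, products):
    blk = config.get("fit", {})
    table = blk.get("input")
    if not table or not Path(table).exists():
        raise ConfigurationError("fit stage needs fit.input pointing at a (delta, fct) CSV")
    df = pd.read_csv(table)
    res = calibration.fit_ct_parameters(
        df["delta"].to_numpy(),
        df["fct"].to_numpy(),
        fix_delta0=blk.get("fix_delta0", False),
        log_space=blk.get("log_space", False),
    )
    params = res.to_ct_params(blk.get("pair_kind", "fit"), functional=blk.get("functional", "fit"))
    path = Path(str(prefix) + "_fit.json")
    cec_core.save_ct_params([params], path)
    products["fit"] = path
    products["_fit_result"] = res


def _stage_grid(config, prefix, products):
    blk = config.get("grid", {})
    pair = blk.get("pair", "h3o-water")
    if pair == "h3o-water":
        grid = calibration.generate_h3o_water_grid()
    elif pair == "glu-water":
        grid = calibration.generate_glu_water_grid()
    else:
        raise ConfigurationError(f"unknown grid pair {pair!r}")
    xyz = Path(str(prefix) + f"_grid_{pair}.xyz")
    write_xyz_trajectory(grid.geometries, xyz)
    csv = Path(str(prefix) + f"_grid_{pair}.csv")
    grid.to_dataframe().to_csv(csv, index=False, float_format="%.10g")
    products["grid_xyz"] = xyz
    products["grid_csv"] = csv


def _stage_metad(config, prefix, seed, products):
    blk = config.get("metad", {})
    demo = biasing.metad_double_well_demo(
        barrier=blk.get("barrier", 3.0),
        seed=seed,
        height=blk.get("height", 0.2),
        width=blk.get("width", 0.1),
        stride_fs=blk.get("stride_fs", 50.0),
        gamma=blk.get("gamma", 12.0),
        n_steps_biased=blk.get("n_steps_biased", 800_000),
        n_steps_unbiased=blk.get("n_steps_unbiased", 40_000),
    )
    result = demo.pop("result")
    hills = Path(str(prefix) + "_hills.csv")
    bias = result.bias
    pd.DataFrame(
        {
            "time_fs": (np.arange(len(bias.centers)) + 1) * bias.stride_fs,
            "center": bias.centers,
            "height": bias.heights,
            "width": bias.width,
        }
    ).to_csv(hills, index=False, float_format="%.10g")
    fes = Path(str(prefix) + "_fes.csv")
    pd.DataFrame({"cv": result.grid, "F": result.free_energy}).to_csv(
        fes, index=False, float_format="%.10g"
    )
    summary = Path(str(prefix) + "_metad_summary.json")
    summary.write_text(json.dumps(demo, indent=2) + "\n")
    products["hills"] = hills
    products["fes"] = fes
    products["metad_summary"] = summary
    products["_metad"] = demo
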