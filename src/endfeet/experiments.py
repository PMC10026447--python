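"""Configuration-driven experiment presets.

Each preset reproduces one computational experiment end to end and writes
tidy CSV tables plus a JSON manifest (config, seed, library versions) into
an output directory.  Identical config and seed give identical tables.

Presets
-------
``vessel_ensembles``
    Gap metrics for the three reference vessel classes (capillary
    r_o=2.9 µm / A=50 µm², venule 15 / 110, arteriole 15 / 490): 200
    hard-core Voronoi realizations each, with Gamma/normal distribution
    fits.
``gap_fraction_fits``
    Radius sweep of simulated gap fractions for arterial and venous area
    relations and exponential refits phi(r_o) = c1 e^(−c2 r_o) + c3.
``projection_table``
    Monte-Carlo measured-vs-true area correction table.
``network``
    Synthetic microvascular network: flow solve, classification, per-
    segment coefficients, depth-layer summaries and endfoot counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import areas, io, network as net_mod, projection, tessellation

__all__ = ["RunConfig", "run_experiment", "EXPERIMENTS", "VESSEL_CLASSES"]

#: Reference vessel classes: name -> (r_o µm, corrected mean area µm²).
VESSEL_CLASSES = {
    "capillary": (2.9, 50.0),
    "venule": (15.0, 110.0),
    "arteriole": (15.0, 490.0),
}


@dataclass
class RunConfig:
    """One experiment run: a preset name, a seed, parameter overrides."""

    experiment: str
    seed: int = 0
    out_dir: str = "results"
    overrides: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))


def _manifest(config: RunConfig, out: Path) -> None:
    import scipy
    manifest = {
        "config": asdict(config),
        "versions": {
            "endfeet": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _run_vessel_ensembles(config: RunConfig, out: Path) -> dict:
    ov = config.overrides
    n_real = int(ov.get("n_realizations", 200))
    d_g = float(ov.get("d_g_nm", 20.0))
    n_cells = int(ov.get("n_cells", 500))
    rows = []
    metrics = []
    for name, (r_o, A) in VESSEL_CLASSES.items():
        m = tessellation.sheath_metrics(
            r_o, A, d_g_nm=d_g, n_realizations=n_real,
            seed=config.seed, n_cells=n_cells,
        )
        if n_real >= 20 and len(m.area_samples) >= 100:
            fits = tessellation.fit_distributions(m)
        else:  # too few samples for a meaningful fit (quick runs)
            fits = tessellation.DistributionFits(np.nan, np.nan, np.nan, np.nan)
        metrics.append(m)
        rows.append({
            "vessel": name, "r_o_um": r_o, "target_mean_area_um2": A,
            "mean_area_um2": m.mean_area, "phi_g": m.phi_g,
            "phi_perp": m.phi_perp, "gaps_per_ring": m.gaps_per_ring,
            "gamma_shape": fits.area_shape, "gamma_scale": fits.area_scale,
            "phi_norm_mean": fits.phi_mean, "phi_norm_sd": fits.phi_sd,
            "n_realizations": n_real,
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "vessel_ensembles.csv", index=False)
    io.metrics_to_frame(metrics).to_csv(out / "vessel_ensembles_realizations.csv", index=False)
    return {"summary": summary}


def _run_gap_fraction_fits(config: RunConfig, out: Path) -> dict:
    ov = config.overrides
    d_g = float(ov.get("d_g_nm", 20.0))
    n_per_radius = int(ov.get("n_per_radius", 10))
    n_cells = int(ov.get("n_cells", 400))
    radii = {
        "arterial": np.asarray(ov.get("arterial_radii", np.linspace(2.5, 15.0, 8))),
        "venous": np.asarray(ov.get("venous_radii", np.linspace(2.5, 20.0, 8))),
    }
    relations = {"arterial": areas.ARTERIAL_AREA, "venous": areas.VENOUS_AREA}
    sample_rows, fit_rows = [], []
    for kind, r_grid in radii.items():
        rel = relations[kind]
        rs, phis = [], []
        for j, r_o in enumerate(r_grid):
            A = rel(float(r_o), extrapolate=True)
            m = tessellation.sheath_metrics(
                float(r_o), A, d_g_nm=d_g, n_realizations=n_per_radius,
                seed=config.seed + 997 * j, n_cells=n_cells,
            )
            rs.extend([r_o] * n_per_radius)
            phis.extend(m.phi_samples.tolist())
        fit = areas.fit_gap_fraction_model(rs, phis, vessel_kind=kind)
        for r, ph in zip(rs, phis):
            sample_rows.append({"vessel_kind": kind, "r_o_um": r, "phi_g": ph})
        fit_rows.append({"vessel_kind": kind, **fit.to_dict()})
    pd.DataFrame(sample_rows).to_csv(out / "gap_fraction_samples.csv", index=False)
    fits = pd.DataFrame(fit_rows)
    fits.to_csv(out / "gap_fraction_fits.csv", index=False)
    return {"fits": fits}


def _run_projection_table(config: RunConfig, out: Path) -> dict:
    ov = config.overrides
    table = projection.build_area_correction(
        r_o_grid=ov.get("r_o_grid", projection.DEFAULT_RADIUS_GRID),
        A_true_grid=ov.get("A_true_grid"),
        n_realizations=int(ov.get("n_realizations", 50)),
        seed=config.seed,
        n_cells=int(ov.get("n_cells", 200)),
    )
    frame = io.correction_table_to_frame(table)
    frame.to_csv(out / "area_correction_table.csv", index=False)
    return {"table": table, "frame": frame}


def _run_network(config: RunConfig, out: Path) -> dict:
    ov = config.overrides
    params = net_mod.NetworkParams(**ov.get("network_params", {}))
    net = net_mod.generate_synthetic_network(params, seed=config.seed)
    net = net_mod.simplify_network(net)
    flow = net_mod.solve_pressures(net)
    labels = net_mod.classify_segments(net, flow)
    seg = net_mod.assign_transport_coefficients(net, labels, flow)
    layers, totals = net_mod.summarize_layers(net, seg)
    counts = net_mod.endfoot_counts(
        net, seg, astrocyte_density_per_mm3=ov.get("astrocyte_density_per_mm3")
    )
    seg.to_csv(out / "segments_coefficients.csv", index=False)
    layers.to_csv(out / "layer_summaries.csv", index=False)
    (out / "network_totals.json").write_text(
        json.dumps({"totals": totals, "endfoot_counts": counts}, indent=1)
    )
    io.write_network(net, out / "network")
    return {"net": net, "flow": flow, "segments": seg, "layers": layers,
            "totals": totals, "counts": counts}


EXPERIMENTS = {
    "vessel_ensembles": _run_vessel_ensembles,
    "gap_fraction_fits": _run_gap_fraction_fits,
    "projection_table": _run_projection_table,
    "network": _run_network,
}


def run_experiment(config: RunConfig) -> dict:
    """Run one preset; returns the in-memory results and writes CSV tables
    plus ``manifest.json`` to ``config.out_dir``."""
    if config.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {config.experiment!r}; "
            f"valid names: {sorted(EXPERIMENTS)}"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = EXPERIMENTS[config.experiment](config, out)
    _manifest(config, out)
    return result
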