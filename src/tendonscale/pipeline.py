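"""End-to-end synthetic study: loading/healing groups -> multiscale metrics.

Runs the whole chain for a configurable design of healing states x loading
groups: generate force-displacement records, extract cyclic and equilibrium
metrics, fit the fiber recruitment model, image synthetic collagen/nuclei
fields at 1% and 10% strain, simulate cell contraction in group-specific
fibrous matrices to get the displacement-decay exponent eta, and feed a
per-specimen table into the stepwise regression stage.

Group conditions encode the study's qualitative biology: high-magnitude
long-duration (fatigue) loading elevates fiber slack lengths, flattens the
equilibrium-stress gain between 1% and 10% strain, makes collagen and
nuclear organization strain-insensitive, and lengthens the constitutive toe
(lower E_f/E_b, higher lambda2 - lambda1), which shortens stress
transmission (larger eta).  Healing raises cellularity, disorganization and
F-actin while also shortening transmission; scaling eta by inter-cell
spacing (eta_eff) compresses the spread between groups.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constitutive import FibrousMatrixParams
from .contraction import (CellGeometry, MeshSpec, build_mesh, solve_contraction,
                          radial_profile, fit_power_law, effective_decay)
from .imaging import (circular_stats, realignment_transition, segment_nuclei,
                      shg_orientation, stack_orientations, factin_fraction)
from .mechanics import (cycle_metrics, frequency_sweep_metrics, strain_stiffening)
from .recruitment import fit_recruitment
from .regression import backward_stepwise
from .synthetic import (LoadingProtocol, SyntheticTruth, gen_force_displacement,
                        gen_nuclei_image, gen_polarizer_stack, gen_shg_image)


@dataclass(frozen=True)
class GroupCondition:
    """Study-condition ground truth for one healing x loading group."""

    healing: str                  # uninjured | wk2 | wk6
    loading: str                  # quasi | low/1k | high/1k
    cyclic_magnitude: str
    cycle_count: int
    # fibrous matrix driving the contraction model
    E_b: float = 1.0              # MPa
    E_f: float = 30.0             # MPa
    lambda1: float = 1.0
    lambda2: float = 1.005
    n_exp: float = 2.0
    m_exp: float = 10.0
    cellularity: float = 300.0    # cells / mm^2
    # collagen organization (von Mises concentration at 1% / 10% strain)
    fiber_kappa_1: float = 4.0
    fiber_kappa_10: float = 8.0
    realignment_strain: float = 3.0   # % strain at the CSD breakpoint
    # nuclei at 1% / 10% strain
    nAR_1: float = 2.6
    nAR_10: float = 3.4
    nuclei_kappa_1: float = 3.0
    nuclei_kappa_10: float = 5.0
    factin_density: float = 0.004     # filament segments / px
    damage_mu_per_decade: float = 0.0

    def matrix_params(self) -> FibrousMatrixParams:
        return FibrousMatrixParams.from_youngs(
            E_b=self.E_b, E_f=self.E_f, lambda1=self.lambda1,
            lambda2=self.lambda2, n=self.n_exp, m=self.m_exp)


def default_groups() -> list[GroupCondition]:
    """Uninjured and 2-week-healing tendon under quasi-static, low/1k and
    high/1k loading, with fatigue and healing effects per the study design."""
    base = dict(E_b=1.0, E_f=30.0, lambda1=1.0, lambda2=1.005)
    heal = dict(E_b=0.5, E_f=3.0, lambda1=1.0, lambda2=1.02,
                cellularity=900.0, fiber_kappa_1=2.5, fiber_kappa_10=2.8,
                nAR_1=2.0, nAR_10=2.6, nuclei_kappa_1=1.5, nuclei_kappa_10=1.8,
                factin_density=0.008)
    fatigue = dict(E_f=1.0, lambda1=1.01, lambda2=1.06,
                   fiber_kappa_10=4.5, realignment_strain=5.0,
                   nAR_10=2.7, nuclei_kappa_1=2.0, nuclei_kappa_10=2.2,
                   damage_mu_per_decade=0.10)
    groups = [
        GroupCondition("uninjured", "quasi", "zero", 0, **base),
        GroupCondition("uninjured", "low/1k", "low", 1000,
                       **{**base, "E_f": 20.0, "lambda2": 1.008}),
        GroupCondition("uninjured", "high/1k", "high", 1000,
                       **{**base, **fatigue}),
        GroupCondition("wk2", "quasi", "zero", 0, **heal),
        GroupCondition("wk2", "high/1k", "high", 1000,
                       **{**heal, "E_f": 1.0, "lambda2": 1.06,
                          "realignment_strain": 5.0,
                          "damage_mu_per_decade": 0.10}),
    ]
    return groups


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "study_out"
    groups: list[GroupCondition] = field(default_factory=default_groups)
    n_specimens: int = 12             # per group, regression stage
    target_strain: float = 10.0
    force_noise_sd: float = 0.01      # N
    mesh: MeshSpec = field(default_factory=lambda: MeshSpec(1.0, 6.0, 100.0))
    cell: CellGeometry = field(default_factory=CellGeometry)
    fe_increments: int = 5
    polarizer_strains: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0)
    polarizer_amplitude: float = 120.0
    image_seed_jitter: int = 101

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, (GroupCondition, MeshSpec, CellGeometry)):
                return asdict(o) if not isinstance(o, (MeshSpec, CellGeometry)) \
                    else o.__dict__ | {"_type": type(o).__name__}
            return str(o)
        blob = json.dumps(asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _group_truth(g: GroupCondition) -> SyntheticTruth:
    return SyntheticTruth(damage_mu_per_decade=g.damage_mu_per_decade)


def _kappa_profile(g: GroupCondition, strain: float) -> float:
    """Fiber concentration vs strain: flat until the realignment strain,
    then rising linearly toward the 10%-strain value."""
    if strain <= g.realignment_strain:
        return g.fiber_kappa_1
    frac = (strain - g.realignment_strain) / max(10.0 - g.realignment_strain,
                                                 1e-9)
    return g.fiber_kappa_1 + frac * (g.fiber_kappa_10 - g.fiber_kappa_1)


def run_group(g: GroupCondition, cfg: RunConfig, seed: int) -> dict:
    """All pipeline stages for one group; returns the summary row."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(8)]
    truth = _group_truth(g)

    # --- macroscale mechanics
    protocol = LoadingProtocol(cyclic_magnitude=g.cyclic_magnitude,
                               cycle_count=g.cycle_count,
                               target_strain=cfg.target_strain)
    record = gen_force_displacement(truth, protocol,
                                    noise_sd=cfg.force_noise_sd, seed=seeds[0])
    stiff = strain_stiffening(record)
    sweep = frequency_sweep_metrics(record, protocol.sweep_frequencies)
    e_star_1hz = float(sweep.loc[sweep["frequency_Hz"] == 1.0,
                                 "E_star_MPa"].iloc[0])
    tan_delta = float(sweep.loc[sweep["frequency_Hz"] == 1.0,
                                "tan_delta"].iloc[0])
    laxity = np.nan
    if g.cycle_count > 0:
        cyc = cycle_metrics(record, protocol.frequency)
        laxity = float(cyc.per_cycle["laxity"].iloc[-1])

    # --- recruitment fit on the final quasi-static ramp
    mask = record.segment(f"ramp_{cfg.target_strain:g}")
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        rec_fit = fit_recruitment(record.displacement[mask], record.force[mask],
                                  gauge_length=truth.gauge_length)

    # --- polarized light: CSD vs strain -> realignment transition
    csd_vs_strain = []
    for i, strain in enumerate(cfg.polarizer_strains):
        kappa = _kappa_profile(g, strain)
        stack, st_truth = gen_polarizer_stack(
            0.0, kappa, n_angles=30, region_grid=(6, 6), region_px=10,
            noise_sd=2.0, seed=seeds[1] + i * cfg.image_seed_jitter,
            amplitude=cfg.polarizer_amplitude)
        df = stack_orientations(stack, st_truth.angles_deg, spacing_px=10)
        ok = df.loc[~df["low_signal"], "theta_deg"]
        if len(ok) < 2:
            raise ValueError("polarized-light stage: all regions low-signal "
                             "(zero-contrast stack)")
        csd_vs_strain.append(circular_stats(ok, period_deg=90.0).csd_deg)
    trans = realignment_transition(np.asarray(cfg.polarizer_strains),
                                   np.asarray(csd_vs_strain))

    # --- SHG collagen organization at 1% and 10% strain
    csd = {}
    for strain, kappa in ((1.0, g.fiber_kappa_1), (10.0, g.fiber_kappa_10)):
        img, _ = gen_shg_image(0.0, kappa, seed=seeds[2] + int(strain))
        _, _, stats = shg_orientation(img)
        csd[strain] = stats.csd_deg

    # --- nuclei at 1% and 10% strain
    nuc = {}
    for strain, (nar, kap) in ((1.0, (g.nAR_1, g.nuclei_kappa_1)),
                               (10.0, (g.nAR_10, g.nuclei_kappa_10))):
        labels, _ = gen_nuclei_image(120, nAR_mean=nar, nAR_sd=0.3,
                                     angle_concentration=kap,
                                     seed=seeds[3] + int(strain))
        table, stats = segment_nuclei(labels)
        nuc[strain] = (float(table["nAR"].mean()), stats.csd_deg)

    # --- F-actin
    fa_img, _ = gen_shg_image(0.0, 2.0, fiber_density=g.factin_density,
                              seed=seeds[4])
    factin = factin_fraction(fa_img)

    # --- cell contraction FE -> decay exponent
    mesh = build_mesh(cfg.cell, cfg.mesh)
    fld = solve_contraction(mesh, g.matrix_params(), cfg.cell,
                            increments=cfg.fe_increments)
    decay = fit_power_law(radial_profile(fld))
    ref_cell = min(gg.cellularity for gg in cfg.groups)
    eta_eff = effective_decay(decay.eta, g.cellularity, ref_cell)

    return {
        "healing": g.healing, "loading": g.loading,
        "s_eq_1": stiff.s_eq[1.0], "s_eq_10": stiff.s_eq[10.0],
        "delta_s_eq": stiff.delta_s_eq,
        "E_star_MPa": e_star_1hz, "tan_delta": tan_delta, "laxity": laxity,
        "SL_mn": rec_fit.params.mu, "SL_sd": rec_fit.params.sigma,
        "realignment_strain": trans.transition,
        "CSD_1": csd[1.0], "CSD_10": csd[10.0],
        "delta_CSD": csd[10.0] - csd[1.0],
        "nAR_1": nuc[1.0][0], "nAR_10": nuc[10.0][0],
        "delta_nAR": nuc[10.0][0] - nuc[1.0][0],
        "nCSD_1": nuc[1.0][1], "nCSD_10": nuc[10.0][1],
        "delta_nCSD": nuc[10.0][1] - nuc[1.0][1],
        "f_actin_pct": factin, "cellularity": g.cellularity,
        "eta": decay.eta, "eta_eff": eta_eff,
        "eta_fit_r2": decay.r_squared,
    }


def build_specimen_table(summary: pd.DataFrame, cfg: RunConfig,
                         seed: int) -> pd.DataFrame:
    """Per-specimen table: group-level values plus specimen noise, with nAR
    generated from cellularity, nuclear disorganization and healing."""
    rng = np.random.default_rng(seed)
    rows = []
    for _, row in summary.iterrows():
        for _ in range(cfg.n_specimens):
            cell = row["cellularity"] * (1 + 0.10 * rng.standard_normal())
            ncsd = row["nCSD_1"] * (1 + 0.10 * rng.standard_normal())
            heal_eff = {"uninjured": 0.0, "wk2": -0.6, "wk6": -0.3}.get(
                row["healing"], 0.0)
            nar = (3.2 - 0.0012 * cell - 0.03 * ncsd + heal_eff
                   + 0.08 * rng.standard_normal())
            rows.append({
                "s_eq": row["s_eq_10"] * (1 + 0.05 * rng.standard_normal()),
                "delta_s_eq": row["delta_s_eq"]
                              * (1 + 0.05 * rng.standard_normal()),
                "E_star": row["E_star_MPa"] * (1 + 0.05 * rng.standard_normal()),
                "tan_delta": row["tan_delta"]
                             * (1 + 0.05 * rng.standard_normal()),
                "CSD": row["CSD_1"] * (1 + 0.08 * rng.standard_normal()),
                "delta_CSD": row["delta_CSD"]
                             + 0.3 * rng.standard_normal(),
                "cellularity": cell,
                "f_actin": row["f_actin_pct"]
                           * (1 + 0.08 * rng.standard_normal()),
                "SL_mn": row["SL_mn"] * (1 + 0.04 * rng.standard_normal()),
                "nCSD": ncsd,
                "delta_nCSD": row["delta_nCSD"] + 0.3 * rng.standard_normal(),
                "healing": row["healing"], "loading": row["loading"],
                "nAR": nar,
            })
    return pd.DataFrame(rows)


def run_study(cfg: RunConfig) -> dict:
    """Run every group, the regression stage, and write the report bundle.

    Returns {"summary": DataFrame, "regression": StepwiseResult,
    "specimens": DataFrame, "provenance": dict}; everything is also written
    under ``cfg.output_dir`` (summary.csv, specimens.csv, regression.json,
    provenance.json), each stamped with the config hash.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    ss = np.random.SeedSequence(cfg.seed)
    group_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(len(cfg.groups) + 1)]

    rows = []
    for g, gseed in zip(cfg.groups, group_seeds):
        try:
            rows.append(run_group(g, cfg, gseed))
        except Exception as e:
            raise RuntimeError(
                f"stage failure in group {g.healing}/{g.loading}: {e}") from e
    summary = pd.DataFrame(rows)

    specimens = build_specimen_table(summary, cfg, group_seeds[-1])
    reg = backward_stepwise(specimens, "nAR", screen_alpha=0.05)

    provenance = {
        "config_hash": chash, "seed": cfg.seed, "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "effective_decay_scaling": "eta_eff = eta * sqrt(ref/cellularity) "
                                   "(areal inter-cell spacing rule)",
    }
    summary.insert(0, "config_hash", chash)
    specimens.insert(0, "config_hash", chash)
    summary.to_csv(out / "summary.csv", index=False)
    specimens.to_csv(out / "specimens.csv", index=False)
    (out / "regression.json").write_text(json.dumps({
        "config_hash": chash,
        "retained": reg.retained,
        "r_squared": reg.r_squared,
        "durbin_watson": reg.durbin_watson,
        "dw_flag": reg.dw_flag,
        "coefficients": {k: float(v) for k, v in reg.coefficients.items()},
    }, indent=2))
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return {"summary": summary, "regression": reg, "specimens": specimens,
            "provenance": provenance}
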