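"""Two-stage analysis orchestration.

Stage 1 (backbone): classify the conformer pool, deconvolute populations
from NOE/J restraints, report the folded beta-hairpin percentage.
Stage 2 (side chain): fit the alignment tensor and populations against
RDCs on the (optionally XB-enriched) pool, report Q, CN and the
halogen-bonded percentage.  Energetics converts folded fractions into
Boltzmann stabilization energies.

Each stage takes a plain configuration mapping (usually loaded from
YAML) and returns a JSON-serializable report; ``run_full`` chains them
and attaches provenance (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .classify import (
    VdwTable,
    XbCriteria,
    classify_folded,
    classify_xb,
    default_hairpin_criteria,
)
from .deconvolution import (
    build_design_matrix,
    fit_populations,
    folded_fraction,
)
from .energetics import (
    EnergeticsConfig,
    boltzmann_ddg,
    correlation_report,
    fold_ratio,
)
from .errors import ConfigError, HairpinXbError, InsufficientDataError
from .observables import (
    KarplusCoefficients,
    read_j_csv,
    read_noe_series_csv,
    read_rdc_csv,
    reduce_noe_series,
    write_j_csv,
    write_noe_series_csv,
    write_rdc_csv,
)
from .rdc import fit_tensor_and_populations, xb_population
from .structures import read_conformer_pool, write_conformer_pool
from .synthetic import (
    GeneratorConfig,
    NoiseModel,
    enrich_with_xb_conformers,
    sample_pool,
    simulate_observables,
)

log = logging.getLogger("hairpinxb")

REPORT_SCHEMA_VERSION = 1

_KNOWN_KEYS = {
    "seed", "output_dir", "pool", "noe_series", "j_table", "rdc_table",
    "karplus", "criteria", "fit", "energetics", "simulate",
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("run configuration must be a mapping")
    return validate_config(cfg)


def validate_config(cfg: Mapping[str, Any]) -> dict:
    for key in cfg:
        if key not in _KNOWN_KEYS:
            raise ConfigError(f"unknown configuration key {key!r}")
    return dict(cfg)


def _karplus_from(cfg: Mapping[str, Any]) -> KarplusCoefficients:
    k = cfg.get("karplus") or {}
    return KarplusCoefficients(
        A=float(k.get("A", 6.51)), B=float(k.get("B", -1.76)),
        C=float(k.get("C", 1.60)), phase=float(k.get("phase", -60.0)),
    )


def _criteria_from(cfg: Mapping[str, Any], n_residues: int):
    c = cfg.get("criteria") or {}
    hp = c.get("hairpin") or {}
    crit = default_hairpin_criteria(
        n_residues=n_residues, turn_position=int(hp.get("turn_position", 6))
    )
    if "turn_tolerance" in hp:
        crit.turn_tolerance = float(hp["turn_tolerance"])
    if "max_mean_ca_ca" in hp:
        crit.max_mean_ca_ca = float(hp["max_mean_ca_ca"])
    if "min_hbonds" in hp:
        crit.min_hbonds = int(hp["min_hbonds"])
    return crit


def _xb_selectors(cfg: Mapping[str, Any]):
    c = cfg.get("criteria") or {}
    donor = c.get("donor") or {}
    acceptor = c.get("acceptor") or {}
    d_res = int(donor.get("res", 4))
    a_res = int(acceptor.get("res", 9))
    return (
        ((d_res, donor.get("c_atom", "CD2")), (d_res, donor.get("x_atom", "XD"))),
        (a_res, acceptor.get("atom", "Y")),
    )


def _config_hash(cfg: Mapping[str, Any]) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _pct(x: float) -> dict[str, float]:
    return {"percent": round(x, 1), "raw": float(x)}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_backbone_stage(cfg: Mapping[str, Any]) -> dict:
    """NOE/J deconvolution stage: returns populations and folded %."""
    cfg = validate_config(cfg)
    if "pool" not in cfg or "noe_series" not in cfg:
        raise ConfigError("backbone stage needs 'pool' and 'noe_series' paths")
    pool = read_conformer_pool(cfg["pool"])
    n_residues = max(a.res_index for a in pool[0].atoms)
    crit = _criteria_from(cfg, n_residues)
    labels = [classify_folded(c, crit) for c in pool]

    series = read_noe_series_csv(cfg["noe_series"])
    fit_cfg = cfg.get("fit") or {}
    noe = reduce_noe_series(
        series,
        rel_error=float(fit_cfg.get("noe_rel_error", 0.10)),
        rate_rel_error=fit_cfg.get("noe_rate_rel_error"),
    )
    j = []
    if cfg.get("j_table"):
        j = read_j_csv(cfg["j_table"])
    else:
        log.warning("no J table configured; running NOE-only backbone fit")
    m = build_design_matrix(pool, noe, j, _karplus_from(cfg))
    lam = fit_cfg.get("lambda_sum")
    fit = fit_populations(m, None if lam is None else float(lam))
    ff = folded_fraction(fit, labels)
    return {
        "stage": "backbone",
        "n_conformers": len(pool),
        "n_noe": len(noe),
        "n_j": len(j),
        "conformer_ids": pool.ids(),
        "folded_labels": [bool(b) for b in labels],
        "populations": [float(p) for p in fit.populations],
        "folded": _pct(ff),
        "rmsd_by_kind": fit.rmsd_by_kind,
        "sum_deviation": fit.sum_deviation,
        "condition_flag": fit.condition_flag,
        "condition_number": fit.condition_number,
    }


def run_sidechain_stage(cfg: Mapping[str, Any], backbone_report: Mapping[str, Any]) -> dict:
    """RDC tensor/population stage: returns tensor, Q, CN and XB %."""
    cfg = validate_config(cfg)
    if backbone_report.get("stage") != "backbone":
        raise ConfigError("side-chain stage requires a completed backbone report")
    if not cfg.get("rdc_table"):
        raise ConfigError("side-chain stage needs an 'rdc_table' path")
    pool = read_conformer_pool(cfg["pool"])
    rdcs = read_rdc_csv(cfg["rdc_table"])
    if len(rdcs) < 5:
        raise InsufficientDataError(
            f"side-chain stage needs >= 5 RDCs, got {len(rdcs)}"
        )
    fit_cfg = cfg.get("fit") or {}
    donor, acceptor = _xb_selectors(cfg)
    xb_crit = XbCriteria(strict=False)
    vdw = VdwTable()
    xb_all = np.array(
        [classify_xb(c, donor, acceptor, vdw, xb_crit) for c in pool]
    )

    mode = fit_cfg.get("sidechain_mode", "staged")
    if mode not in ("staged", "free"):
        raise ConfigError(f"unknown sidechain_mode {mode!r}")
    if mode == "staged":
        # two-stage strategy: keep only conformers the backbone fit
        # populated, plus the XB-constrained side-chain variants, and pin
        # the folded total at the backbone-stage value
        floor = float(fit_cfg.get("population_floor", 1e-3))
        bb_pop = np.array(backbone_report["populations"])
        if len(bb_pop) != len(pool):
            raise ConfigError(
                "backbone report does not match the side-chain pool size"
            )
        keep = sorted(
            {i for i in range(len(pool)) if bb_pop[i] > floor}
            | {i for i in range(len(pool)) if xb_all[i]}
        )
        sub = pool.subset(keep)
        folded_sub = np.array([
            classify_folded(c, _criteria_from(cfg, max(a.res_index for a in c.atoms)))
            for c in sub
        ])
        constraints = [(folded_sub, backbone_report["folded"]["raw"] / 100.0)]
    else:
        keep = list(range(len(pool)))
        sub = pool
        constraints = []
    fit = fit_tensor_and_populations(
        sub, rdcs,
        max_iter=int(fit_cfg.get("max_iter", 200)),
        tol=float(fit_cfg.get("tol", 1e-12)),
        group_constraints=constraints,
    )
    xb_labels = [bool(xb_all[i]) for i in keep]
    xb = xb_population(fit, xb_labels)
    flags = []
    if not fit.reliable:
        flags.append("cn_unreliable")
    if fit.q_class == "poor":
        flags.append("q_poor")
    return {
        "stage": "sidechain",
        "mode": mode,
        "n_conformers": len(sub),
        "kept_indices": [int(i) for i in keep],
        "n_rdc": len(rdcs),
        "xb_labels": [bool(b) for b in xb_labels],
        "populations": [float(p) for p in fit.populations],
        "tensor": [float(s) for s in fit.tensor.s],
        "q": fit.q,
        "q_class": fit.q_class,
        "cn": fit.cn,
        "xb": _pct(xb),
        "d_calc": [float(v) for v in fit.d_calc],
        "flags": flags,
        "n_iter": fit.n_iter,
    }


def run_energetics(cfg: Mapping[str, Any], folded_percent: float) -> dict:
    """Boltzmann energetics of the fitted folded fraction vs a reference."""
    e = cfg.get("energetics") or {}
    ecfg = EnergeticsConfig(
        T=float(e.get("T", 298.15)),
        convention=e.get("convention", "population_ratio"),
    )
    report: dict[str, Any] = {"stage": "energetics", "convention": ecfg.convention,
                              "T": ecfg.T}
    p = folded_percent / 100.0
    if "reference_folded_percent" in e:
        p_ref = float(e["reference_folded_percent"]) / 100.0
        report["ddG_kJ_mol"] = boltzmann_ddg(p, p_ref, ecfg)
        ratio, rendering = fold_ratio(p, p_ref)
        report["fold_ratio"] = ratio
        report["fold_ratio_rendered"] = rendering
    if "dde" in e and "xb_percents" in e:
        report["correlation"] = correlation_report(e["dde"], e["xb_percents"])
    return report


def run_full(cfg: Mapping[str, Any]) -> dict:
    """Backbone fit -> side-chain RDC fit -> energetics, with provenance."""
    cfg = validate_config(cfg)
    stages: dict[str, Any] = {}
    try:
        stages["backbone"] = run_backbone_stage(cfg)
    except HairpinXbError as exc:
        raise type(exc)(f"[backbone] {exc}") from exc
    if cfg.get("rdc_table"):
        try:
            stages["sidechain"] = run_sidechain_stage(cfg, stages["backbone"])
        except HairpinXbError as exc:
            raise type(exc)(f"[sidechain] {exc}") from exc
    stages["energetics"] = run_energetics(cfg, stages["backbone"]["folded"]["raw"])
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "config_hash": _config_hash(cfg),
            "seed": cfg.get("seed"),
            "package": "hairpinxb",
            "version": _package_version(),
        },
        **stages,
    }


def _package_version() -> str:
    from . import __version__

    return __version__


# ---------------------------------------------------------------------------
# simulation entry point (writes a complete synthetic data set)
# ---------------------------------------------------------------------------

def run_simulate(cfg: Mapping[str, Any]) -> dict:
    """Generate a pool + restraint tables + ground truth under ``output_dir``.

    The ``simulate`` block accepts the GeneratorConfig and NoiseModel
    fields plus ``n_xb_enrich`` for appended XB-constrained conformers.
    """
    cfg = validate_config(cfg)
    sim = dict(cfg.get("simulate") or {})
    seed = cfg.get("seed", sim.pop("seed", None))
    if seed is None:
        raise ConfigError("simulation requires a seed")
    outdir = Path(cfg.get("output_dir", "."))
    outdir.mkdir(parents=True, exist_ok=True)

    n_enrich = int(sim.pop("n_xb_enrich", 0))
    xb_truth = float(sim.pop("xb_truth_percent", 30.0)) / 100.0
    noise = NoiseModel(
        noe_rate_rel=float(sim.pop("noe_rate_rel", 0.05)),
        j_hz=float(sim.pop("j_hz", 0.3)),
        rdc_hz=float(sim.pop("rdc_hz", 0.3)),
    )
    gen = GeneratorConfig(seed=int(seed), **sim)
    pool, truth = sample_pool(gen)
    if n_enrich > 0:
        pool = enrich_with_xb_conformers(pool, gen, n_enrich, seed=int(seed) + 1)
        extra = len(pool) - len(truth.populations)
        # ground truth gives the XB-constrained appends a fixed share and
        # rescales the original weights to the remainder
        populations = np.concatenate([
            truth.populations * (1.0 - xb_truth),
            np.full(extra, xb_truth / extra),
        ])
        from .synthetic import GroundTruth, _xb_label

        truth = GroundTruth(
            populations / populations.sum(),
            truth.tensor,
            np.array([bool(b) for b in truth.folded_labels] + [True] * extra),
            np.array([_xb_label(c, gen) for c in pool]),
        )
    obs = simulate_observables(pool, truth, noise, seed=int(seed) + 2)

    pool_path = outdir / "pool.pdb"
    write_conformer_pool(pool, pool_path)
    write_noe_series_csv(obs.noe_series, outdir / "noe_series.csv")
    write_j_csv(obs.j, outdir / "j.csv")
    write_rdc_csv(obs.rdc, outdir / "rdc.csv")
    truth_blob = {
        "populations": [float(p) for p in truth.populations],
        "tensor": [float(s) for s in truth.tensor.s],
        "folded_labels": [bool(b) for b in truth.folded_labels],
        "xb_labels": [bool(b) for b in truth.xb_labels],
        "folded_percent": float(100 * truth.populations[truth.folded_labels].sum()),
        "xb_percent": float(100 * truth.populations[truth.xb_labels].sum()),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_blob, fh, indent=2)
    return {
        "pool": str(pool_path),
        "noe_series": str(outdir / "noe_series.csv"),
        "j_table": str(outdir / "j.csv"),
        "rdc_table": str(outdir / "rdc.csv"),
        "truth": str(outdir / "truth.json"),
        "n_conformers": len(pool),
    }
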