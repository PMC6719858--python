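"""Config-driven analysis pipeline chaining every module into one report.

A single YAML (or JSON) config enables any subset of analysis blocks;
each enabled block writes exactly one artifact (TSV or JSON) into the
output directory, failures are collected per block without aborting the
others, and a provenance record (config hash, package version, seed)
makes deterministic blocks re-runnable bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _VERSION
from . import binding_assays, mtdna_tools, reference, sasa_charge, synthetic_data, traj_metrics
from .structure_io import read_pdb, to_trajectory, write_pdb

__all__ = ["RunConfig", "ReportBundle", "ConfigError", "validate_config", "run_analysis", "demo"]

log = logging.getLogger("ssbkit")


class ConfigError(ValueError):
    """Aggregated configuration problems (unknown keys, bad ranges, missing files)."""


# block -> option -> (default, checker); checker returns an error string or None
def _pos(lo, hi):
    return lambda v: None if (isinstance(v, (int, float)) and lo <= v <= hi) else f"must be in [{lo}, {hi}]"


def _is_path(v):
    return None if Path(v).exists() else f"file not found: {v}"


_ANY = lambda v: None

_SCHEMA: dict[str, dict[str, tuple]] = {
    "trajectory": {
        "traj_pdb": (None, _is_path),
        "window": (1.0 / 3.0, _pos(0.0, 1.0)),
        "threshold": (2.0, _pos(0.0, 100.0)),
        "rmsd_tolerance": (0.5, _pos(0.0, 100.0)),
    },
    "sasa": {
        "pdb": (None, _is_path),
        "probe": (1.4, _pos(0.0, 10.0)),
        "n_points": (960, _pos(16, 100000)),
        "mode": ("ca_spheres", lambda v: None if v in ("vdw", "ca_spheres") else "must be vdw|ca_spheres"),
        "window": (1.0 / 3.0, _pos(0.0, 1.0)),
    },
    "charge": {
        "fasta": (None, _is_path),  # None -> bundled canonical SSBP1
        "range": ([26, 140], _ANY),
        "copies": (4, _pos(1, 8)),
        "mutation": ("E27K", _ANY),
    },
    "isotherm": {
        "csv": (None, _is_path),
        "dna_nM": (20.0, _pos(1e-6, 1e6)),
    },
    "dsf": {
        "csv": (None, _is_path),
        "prominence_fraction": (0.05, _pos(0.0, 1.0)),
    },
    "ddpcr": {
        "tsv": (None, _is_path),
        "method": ("poisson_ratio", lambda v: None if v in ("poisson_ratio", "raw_ratio") else "must be poisson_ratio|raw_ratio"),
    },
    "coverage": {
        "tsv": (None, _is_path),
        "drop_fraction": (0.3, _pos(0.0, 1.0)),
        "min_length": (1000, _pos(1, 10**7)),
    },
    "copynumber": {
        "tsv": (None, _is_path),
        "control": (None, _ANY),
        "sample": (None, _ANY),
    },
    "deletion": {
        "label": ("m.8629_14068del5440", _ANY),
    },
}

_TOP_KEYS = {"seed", "out_dir"} | set(_SCHEMA)


@dataclass
class RunConfig:
    seed: int
    out_dir: Path
    blocks: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d: dict = {"seed": self.seed, "out_dir": str(self.out_dir)}
        for name, opts in self.blocks.items():
            d[name] = {
                k: (str(v) if isinstance(v, Path) else v) for k, v in opts.items() if v is not None
            }
        return d

    @property
    def config_hash(self) -> str:
        """Path-independent hash: options and input basenames, not locations."""
        d = self.to_dict()
        d.pop("out_dir", None)
        for opts in d.values():
            if isinstance(opts, dict):
                for k, v in opts.items():
                    if isinstance(v, str) and ("/" in v or "\\" in v):
                        opts[k] = Path(v).name
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def validate_config(source) -> RunConfig:
    """Validate a YAML/JSON config file path, or a dict, into a RunConfig.

    Unknown top-level or block keys, out-of-range options and missing
    input files are all reported together in one ConfigError.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    problems: list[str] = []
    for key in raw:
        if key not in _TOP_KEYS:
            problems.append(f"unknown key {key!r}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append("seed must be an integer")
    out_dir = Path(raw.get("out_dir", "ssbkit_out"))
    blocks: dict[str, dict] = {}
    for name, schema in _SCHEMA.items():
        if name not in raw:
            continue
        given = raw[name] or {}
        if not isinstance(given, dict):
            problems.append(f"{name}: block must be a mapping")
            continue
        opts = {}
        for k, v in given.items():
            if k not in schema:
                problems.append(f"{name}: unknown key {k!r}")
        for k, (default, check) in schema.items():
            v = given.get(k, default)
            if v is not None and k in given:
                err = check(v)
                if err:
                    problems.append(f"{name}.{k}: {err}")
            opts[k] = v
        blocks[name] = opts
    if problems:
        raise ConfigError("invalid config:\n  " + "\n  ".join(problems))
    return RunConfig(seed=seed, out_dir=out_dir, blocks=blocks)


@dataclass
class ReportBundle:
    out_dir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, sort_keys=True, indent=2, default=float) + "\n")


def _write_tsv(path: Path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def _parse_mutation(text: str) -> tuple[int, str, str]:
    wt, pos, mut = text[0], int(text[1:-1]), text[-1]
    return pos, wt.upper(), mut.upper()


# ---------------------------------------------------------------------------
# blocks


def _run_trajectory(opts: dict, out: Path, meta: dict) -> Path:
    models = read_pdb(opts["traj_pdb"])
    traj = to_trajectory(models, "CA")
    window = float(opts["window"])
    rmsd = traj_metrics.rmsd_series(traj)
    devmap = traj_metrics.ca_deviation_map(traj, window=window)
    fractions = {
        scope: dataclasses.asdict(traj_metrics.pair_mobility_fraction(devmap, opts["threshold"], scope))
        for scope in ("intra_monomer", "inter_monomer", "overall")
    }
    rmsf = traj_metrics.rmsf_profile(traj)
    conv = traj_metrics.convergence_check(rmsd, window=window, tolerance=opts["rmsd_tolerance"])
    _write_tsv(out / "rmsd.tsv", pd.DataFrame({"frame": np.arange(rmsd.size), "rmsd_A": rmsd}), meta)
    labels = [f"{c}{s}" for c, s in devmap.residue_labels]
    dm = pd.DataFrame(devmap.matrix, columns=labels)
    dm.insert(0, "residue", labels)
    _write_tsv(out / "deviation_map.tsv", dm, meta)
    _write_tsv(
        out / "rmsf.tsv",
        pd.DataFrame({
            "residue": [f"{c}{s}" for c, s in rmsf.residue_labels],
            "rmsf_A": rmsf.rmsf, "b_factor_A2": rmsf.b_factor, "normalized_b": rmsf.normalized_b,
        }),
        meta,
    )
    _write_json(out / "trajectory_summary.json", {
        "mobility_fractions": fractions,
        "rmsd_convergence": dataclasses.asdict(conv),
        "n_frames": traj.n_frames,
        "n_residues": len(devmap.residue_labels),
    })
    return out / "trajectory_summary.json"


def _run_sasa(opts: dict, out: Path, meta: dict) -> Path:
    models = read_pdb(opts["pdb"])
    mode = opts["mode"]
    if len(models) > 1:
        traj = to_trajectory(models)
        stats = sasa_charge.trajectory_sasa_decomposition(
            traj, window=float(opts["window"]), probe=opts["probe"],
            n_points=int(opts["n_points"]), mode=mode,
        )
        df = pd.DataFrame({
            "component": list(stats),
            "mean_A2": [stats[k][0] for k in stats],
            "sd_A2": [stats[k][1] for k in stats],
        })
    else:
        res = sasa_charge.shrake_rupley_sasa(models[0], probe=opts["probe"],
                                             n_points=int(opts["n_points"]), mode=mode)
        dec = sasa_charge.sasa_decomposition(res, models[0])
        df = pd.DataFrame({
            "component": ["total", "positive", "negative", "net_positive"],
            "mean_A2": [dec.total, dec.positive, dec.negative, dec.net_positive],
            "sd_A2": [0.0, 0.0, 0.0, 0.0],
        })
    _write_tsv(out / "sasa_table.tsv", df, meta)
    return out / "sasa_table.tsv"


def _run_charge(opts: dict, out: Path, meta: dict) -> Path:
    if opts["fasta"]:
        seq = reference.load_fasta_sequence(opts["fasta"])
    else:
        seq = reference.ssbp1_canonical_sequence()
    start, end = opts["range"]
    construct = seq[start - 1 : end]
    pos, wt, mut = _parse_mutation(opts["mutation"])
    per_mono = sasa_charge.mutation_charge_delta(wt, mut)
    copies = int(opts["copies"])
    net_wt = sasa_charge.net_formal_charge(construct) * copies
    rows = []
    for n_mut in range(5):
        delta = sasa_charge.assembly_charge_delta(n_mut, per_mono)
        rows.append({"n_mutant_monomers": n_mut, "charge_delta_e": delta,
                     "net_charge_e": net_wt + delta})
    df = pd.DataFrame(rows)
    _write_tsv(out / "charge_table.tsv", df, meta)
    return out / "charge_table.tsv"


def _run_isotherm(opts: dict, out: Path, meta: dict) -> Path:
    curve = binding_assays.load_titration_csv(opts["csv"], dna_total=float(opts["dna_nM"]))
    fit = binding_assays.fit_isotherm(curve)
    _write_json(out / "isotherm_fit.json", {
        "kd_apparent_nM": fit.kd_apparent, "kd_sd_nM": fit.kd_sd,
        "a_free": fit.a_free, "a_bound": fit.a_bound,
        "residual_rms": fit.residual_rms, "dna_total_nM": curve.dna_total,
    })
    return out / "isotherm_fit.json"


def _run_dsf(opts: dict, out: Path, meta: dict) -> Path:
    curve = binding_assays.load_melt_csv(opts["csv"])
    tm = binding_assays.find_tm(curve, prominence_fraction=float(opts["prominence_fraction"]))
    _write_json(out / "tm.json", {
        "peaks": [dataclasses.asdict(p) for p in tm.peaks],
        "major_tm_C": tm.major.tm,
    })
    return out / "tm.json"


def _run_ddpcr(opts: dict, out: Path, meta: dict) -> Path:
    assay = mtdna_tools.load_ddpcr_tsv(opts["tsv"])
    est = mtdna_tools.heteroplasmy_from_ddpcr(assay, method=opts["method"])
    _write_json(out / "heteroplasmy.json", dataclasses.asdict(est))
    return out / "heteroplasmy.json"


def _run_coverage(opts: dict, out: Path, meta: dict) -> Path:
    profile = mtdna_tools.load_coverage_tsv(opts["tsv"])
    hits = mtdna_tools.scan_coverage_for_deletion(
        profile, drop_fraction=float(opts["drop_fraction"]), min_length=int(opts["min_length"])
    )
    _write_json(out / "coverage_deletions.json", {
        "candidates": [
            {"label": d.hgvs_label(), "start": d.start, "end": d.end,
             "length_bp": d.length, "depth_ratio": r, "heteroplasmy_proxy": 1.0 - r}
            for d, r in hits
        ]
    })
    return out / "coverage_deletions.json"


def _run_copynumber(opts: dict, out: Path, meta: dict) -> Path:
    table = mtdna_tools.load_ct_tsv(opts["tsv"])
    control = opts["control"] or sorted(table)[0]
    results = {}
    for label, meas in table.items():
        if label == control:
            continue
        if opts["sample"] and label != opts["sample"]:
            continue
        results[label] = mtdna_tools.relative_copy_number(meas, table[control])
    _write_json(out / "copynumber.json", {"control": control, "relative_ratio": results})
    return out / "copynumber.json"


def _run_deletion(opts: dict, out: Path, meta: dict) -> Path:
    deletion = mtdna_tools.parse_deletion_label(opts["label"])
    _write_json(out / "deletion.json", {
        "label": deletion.hgvs_label(), "start": deletion.start,
        "end": deletion.end, "length_bp": deletion.length,
        "genome_length": deletion.genome_length,
    })
    return out / "deletion.json"


_RUNNERS = {
    "trajectory": _run_trajectory,
    "sasa": _run_sasa,
    "charge": _run_charge,
    "isotherm": _run_isotherm,
    "dsf": _run_dsf,
    "ddpcr": _run_ddpcr,
    "coverage": _run_coverage,
    "copynumber": _run_copynumber,
    "deletion": _run_deletion,
}


def run_analysis(config: RunConfig) -> ReportBundle:
    """Execute every enabled block; failures are isolated per block."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash, "ssbkit_version": _VERSION, "seed": config.seed}
    bundle = ReportBundle(out_dir=out, provenance=dict(meta))
    for name in config.blocks:
        runner = _RUNNERS[name]
        try:
            bundle.artifacts[name] = runner(config.blocks[name], out, meta)
            log.info("block %s -> %s", name, bundle.artifacts[name].name)
        except Exception as exc:  # noqa: BLE001 - per-block isolation is the contract
            bundle.errors[name] = f"{type(exc).__name__}: {exc}"
            log.error("block %s failed: %s", name, bundle.errors[name])
    _write_json(out / "provenance.json", {
        **meta,
        "artifacts": {k: str(v.name) for k, v in bundle.artifacts.items()},
        "errors": bundle.errors,
    })
    return bundle


# ---------------------------------------------------------------------------
# synthetic demo


def demo(out_dir, seed: int = 0) -> ReportBundle:
    """Generate synthetic fixtures for every block and run the full pipeline.

    All inputs are drawn from the synthetic_data generators at the given
    seed; with a fixed seed the whole bundle is byte-identical across runs.
    """
    out = Path(out_dir)
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(5)]

    tetramer = synthetic_data.build_toy_tetramer(
        synthetic_data.ToyTetramerSpec(monomer_sequence="AEKARDGLSTVE")
    )
    traj = synthetic_data.simulate_harmonic_trajectory(
        tetramer, synthetic_data.HarmonicTrajSpec(n_frames=120, sigma=0.5, seed=seeds[0])
    )
    traj_path = inputs / "trajectory.pdb"
    write_pdb([traj.frame_model(t) for t in range(traj.n_frames)], traj_path)

    curve = synthetic_data.simulate_titration(synthetic_data.TitrationSimSpec(seed=seeds[1]))
    tit_path = inputs / "titration.csv"
    pd.DataFrame({
        "conc_nM": curve.protein_tetramer_conc,
        "anisotropy": curve.anisotropy,
        "replicate_sd": curve.replicate_sd,
    }).to_csv(tit_path, index=False, float_format="%.6f")

    melt = synthetic_data.simulate_melt_curve(
        synthetic_data.MeltSimSpec(transitions=((61.6, 1.5, 0.25), (75.1, 1.0, 1.0)), seed=seeds[2])
    )
    melt_path = inputs / "melt.csv"
    pd.DataFrame({"temp_C": melt.temperature, "fluorescence": melt.fluorescence}).to_csv(
        melt_path, index=False, float_format="%.6f"
    )

    assay = synthetic_data.simulate_ddpcr(synthetic_data.DdpcrSimSpec(seed=seeds[3]))
    ddpcr_path = inputs / "ddpcr.tsv"
    rows = []
    for i in range(assay.reference_positives.size):
        rows.append({"assay": "in_deletion", "replicate": i + 1,
                     "positives": int(assay.in_deletion_positives[i]),
                     "total": int(assay.in_deletion_totals[i])})
        rows.append({"assay": "reference", "replicate": i + 1,
                     "positives": int(assay.reference_positives[i]),
                     "total": int(assay.reference_totals[i])})
    pd.DataFrame(rows).to_csv(ddpcr_path, sep="\t", index=False)

    profile = synthetic_data.simulate_coverage(synthetic_data.CoverageSimSpec(seed=seeds[4]))
    cov_path = inputs / "coverage.tsv"
    pd.DataFrame({"pos": np.arange(1, profile.genome_length + 1),
                  "depth": profile.depth.astype(int)}).to_csv(cov_path, sep="\t", index=False)

    ct_path = inputs / "ct.tsv"
    pd.DataFrame([
        # proband mt target one cycle later than control -> relative ratio 0.5
        {"sample": "proband", "mt_ct": 21.0, "nuclear_ct": 25.0},
        {"sample": "proband", "mt_ct": 21.1, "nuclear_ct": 25.1},
        {"sample": "proband", "mt_ct": 20.9, "nuclear_ct": 24.9},
        {"sample": "mother", "mt_ct": 20.0, "nuclear_ct": 25.0},
        {"sample": "mother", "mt_ct": 20.1, "nuclear_ct": 25.1},
        {"sample": "mother", "mt_ct": 19.9, "nuclear_ct": 24.9},
    ]).to_csv(ct_path, sep="\t", index=False)

    config = validate_config({
        "seed": seed,
        "out_dir": str(out / "report"),
        "trajectory": {"traj_pdb": str(traj_path)},
        "sasa": {"pdb": str(traj_path)},
        "charge": {},
        "isotherm": {"csv": str(tit_path)},
        "dsf": {"csv": str(melt_path)},
        "ddpcr": {"tsv": str(ddpcr_path)},
        "coverage": {"tsv": str(cov_path)},
        "copynumber": {"tsv": str(ct_path), "control": "mother"},
        "deletion": {},
    })
    return run_analysis(config)
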