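"""End-to-end pipeline orchestration.

Runs simulate -> normalize -> metrics -> classify -> seqdiv -> duptime
on synthetic data with known ground truth, writes every stage's outputs
as TSV/JSON under one output directory, and records a manifest (config
snapshot, per-stage output paths, SHA-256 checksums, record counts).
The manifest contains no timestamps, so two runs with the same config
produce byte-identical outputs and identical checksum sets.
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

from . import duptime as duptime_mod
from . import exprmetrics, fates, normexpr, seqdiv, synth
from .dataset import ExpressionDataset
from .trees import SpeciesTree

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "normalize", "metrics", "classify", "seqdiv", "duptime")
STAGE_DEPS = {
    "normalize": ("simulate",),
    "metrics": ("simulate",),
    "classify": ("metrics",),
    "seqdiv": (),
    "duptime": (),
}

DEFAULT_SCENARIOS = (
    {"name": "ANCESTRAL_PRESERVED_A", "minor_scale": 0.1},
    {"name": "SUBFUNCTIONALIZATION"},
    {"name": "HYPOFUNCTIONALIZATION", "dosage_split": 0.5},
)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGE_ORDER
    # synthetic expression data
    scenarios: tuple[dict, ...] = DEFAULT_SCENARIOS
    n_pairs: int = 50
    n_tissues: int = 9
    noise_sd: float = 0.25
    pre_species: tuple[str, ...] = ("prespecies1", "prespecies2")
    post_species: tuple[str, ...] = tuple(f"postspecies{i+1}" for i in range(12))
    n_single_copy_families: int = 200
    # normalization
    reference_sample: str | None = None
    multimap_threshold: float = 0.2
    n_stable: int = 100
    # classification
    alpha: float = 0.05
    n_perm: int = 2000
    rel_scale: str = "linear"
    # sequence divergence
    n_seqdiv_families: int = 20
    n_codons: int = 500
    omega_major: float = 0.05
    omega_minor: float = 0.5
    omega_pre: float = 0.2
    expected_subs_per_codon: float = 0.45
    min_length_frac: float = 0.5
    cliff_large: float = seqdiv.CLIFF_LARGE_THRESHOLD
    # duplication timing
    tree_newick: str | None = None
    n_duptime_families: int = 10
    n_events: int = 3

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for stage in self.stages:
            missing = [d for d in STAGE_DEPS.get(stage, ()) if d not in self.stages]
            if missing:
                raise ValueError(
                    f"stage {stage!r} requires disabled stage(s) {missing}"
                )
        if self.n_perm < 1 or not (0 < self.alpha < 1):
            raise ValueError("invalid alpha / n_perm")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("stages", "scenarios", "pre_species", "post_species"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


@dataclass
class RunManifest:
    """Record of a pipeline run: config, outputs, checksums, counts."""

    config: dict
    outputs: dict[str, dict[str, str]] = field(default_factory=dict)  # stage -> {name: path}
    checksums: dict[str, str] = field(default_factory=dict)  # path -> sha256
    record_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    stage_log: list[str] = field(default_factory=list)

    def register(self, stage: str, name: str, path: Path) -> None:
        self.outputs.setdefault(stage, {})[name] = str(path)
        self.checksums[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _scenario_from_dict(d: dict, n_tissues: int, noise_sd: float) -> synth.FateScenario:
    d = dict(d)
    name = synth.FateName(d.pop("name"))
    if name is synth.FateName.SUBFUNCTIONALIZATION and "tissue_mask_A" not in d:
        half = n_tissues // 2
        d["tissue_mask_A"] = np.array([True] * half + [False] * (n_tissues - half))
    elif "tissue_mask_A" in d and d["tissue_mask_A"] is not None:
        d["tissue_mask_A"] = np.asarray(d["tissue_mask_A"], dtype=bool)
    return synth.FateScenario(name=name, noise_sd=noise_sd, **d)


def _balanced_newick(names: list[str]) -> str:
    """A deterministic ladder tree over the given leaf names."""
    tree = names[0]
    for name in names[1:]:
        tree = f"({name},{tree})"
    return tree + ";"


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot())
    state: dict = {}
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, out_dir, manifest, state)
            manifest.stage_log.append(f"{stage}: ok")
        except Exception:
            manifest.stage_log.append(f"{stage}: FAILED")
            manifest.write(out_dir / "manifest.json")
            logger.exception("stage %s failed; partial manifest written", stage)
            raise
    manifest.write(out_dir / "manifest.json")
    return manifest


# -- stages ------------------------------------------------------------


def _stage_simulate(config: RunConfig, out_dir: Path, manifest: RunManifest, state: dict) -> None:
    datasets, truths = [], {}
    for i, sc_dict in enumerate(config.scenarios):
        scenario = _scenario_from_dict(sc_dict, config.n_tissues, config.noise_sd)
        ds, truth = synth.simulate_expression_pair_set(
            config.n_pairs,
            scenario,
            n_tissues=config.n_tissues,
            pre_species=config.pre_species,
            post_species=config.post_species,
            seed=config.seed + i,
            n_single_copy_families=(config.n_single_copy_families if i == 0 else 0),
        )
        prefix = scenario.name.value.lower()
        ds.values.index = [f"{prefix}.{g}" for g in ds.values.index]
        ds.gene_meta.index = ds.values.index
        ds.gene_meta["family"] = [f"{prefix}.{f}" for f in ds.gene_meta["family"]]
        og = ds.gene_meta["single_copy_og"]
        ds.gene_meta["single_copy_og"] = og.where(og.isna(), prefix + "." + og.astype(str))
        datasets.append(ds)
        truths.update(
            {f"{prefix}.{k}": v for k, v in truth.expression_scenarios.items()}
        )
    merged = ExpressionDataset(
        values=pd.concat([d.values for d in datasets]),
        gene_meta=pd.concat([d.gene_meta for d in datasets]),
        sample_meta=datasets[0].sample_meta,
        stage="rpkm",
    )
    state["expression"] = merged
    state["truth"] = truths
    paths = merged.write_tsv(out_dir, prefix="simulated")
    for name, p in paths.items():
        manifest.register("simulate", name, p)
    truth_path = out_dir / "simulated_truth.json"
    truth_path.write_text(json.dumps(truths, indent=2, sort_keys=True))
    manifest.register("simulate", "truth", truth_path)
    manifest.record_counts["simulate"] = {
        "families": len(truths),
        "genes": len(merged.genes),
        "samples": len(merged.samples),
    }


def _stage_normalize(config: RunConfig, out_dir: Path, manifest: RunManifest, state: dict) -> None:
    expression = state["expression"]
    counts, fractional = synth.simulate_counts_from_expression(
        expression, seed=config.seed + 101, composition_fraction=0.05
    )
    normalized, report = normexpr.normalize_pipeline(
        counts,
        counts_fractional=fractional,
        reference_sample=config.reference_sample,
        multimap_threshold=config.multimap_threshold,
        n_stable=config.n_stable,
    )
    state["normalized"] = normalized
    paths = normalized.write_tsv(out_dir, prefix="normalized")
    for name, p in paths.items():
        manifest.register("normalize", name, p)
    report_path = out_dir / "normalization_report.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    manifest.register("normalize", "report", report_path)
    manifest.record_counts["normalize"] = {
        "genes_removed_multimap": len(report.removed_multimap),
        "stable_genes": len(report.stable_genes),
    }


def _stage_metrics(config: RunConfig, out_dir: Path, manifest: RunManifest, state: dict) -> None:
    source = state.get("normalized", state["expression"])
    rpkm = source.to_rpkm() if source.stage != "rpkm" else source
    spec_table = exprmetrics.specificity_table(rpkm)
    distances = exprmetrics.build_distance_table(
        rpkm, pre_species=list(config.pre_species), rel_scale=config.rel_scale
    )
    state["distances"] = distances
    spec_path = out_dir / "specificity.tsv"
    spec_table.to_csv(spec_path, sep="\t")
    dist_path = out_dir / "distances.tsv"
    distances.to_csv(dist_path, sep="\t", index=False)
    manifest.register("metrics", "specificity", spec_path)
    manifest.register("metrics", "distances", dist_path)
    manifest.record_counts["metrics"] = {
        "distance_rows": len(distances),
        "genes_with_tau": int(spec_table["tau"].notna().sum()),
    }


def _stage_classify(config: RunConfig, out_dir: Path, manifest: RunManifest, state: dict) -> None:
    calls, summary = fates.classify_all(
        state["distances"], alpha=config.alpha, n_perm=config.n_perm, seed=config.seed
    )
    state["fate_calls"] = calls
    truth = state.get("truth", {})
    if truth:
        summary["true_scenario"] = summary["family"].map(truth)
    summary_path = out_dir / "fate_calls.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)
    manifest.register("classify", "summary", summary_path)
    calls_path = out_dir / "fate_calls.json"
    calls_path.write_text(
        json.dumps(
            [dict(c.to_record(), trace=c.trace) for c in calls],
            indent=2, sort_keys=True,
        )
    )
    manifest.register("classify", "calls", calls_path)
    manifest.record_counts["classify"] = {
        "families": len(calls),
        **{
            cat: sum(1 for c in calls if c.category == cat)
            for cat in fates.CATEGORIES
        },
    }


def _stage_seqdiv(config: RunConfig, out_dir: Path, manifest: RunManifest, state: dict) -> None:
    alignments, pairing_rows = {}, []
    rng = np.random.default_rng(config.seed + 202)
    for k in range(config.n_seqdiv_families):
        family = f"seqfam{k:03d}"
        seqs, rows = synth.simulate_family_codon_set(
            n_codons=config.n_codons,
            expected_subs_per_codon=config.expected_subs_per_codon,
            omega_pre=config.omega_pre,
            omega_a=config.omega_major,
            omega_b=config.omega_minor,
            pre_species=list(config.pre_species),
            post_species=list(config.post_species)[:4],
            seed=int(rng.integers(0, 2**31 - 1)),
            family=family,
        )
        alignments[family] = seqs
        pairing_rows.extend(rows)
    pairing = pd.DataFrame(pairing_rows)
    dn_table = seqdiv.pairwise_dn_table(
        alignments, pairing, min_length_frac=config.min_length_frac
    )
    state["dn_table"] = dn_table
    dn_path = out_dir / "dn_table.tsv"
    dn_table.to_csv(dn_path, sep="\t", index=False)
    manifest.register("seqdiv", "dn_table", dn_path)
    manifest.record_counts["seqdiv"] = {"dn_rows": len(dn_table)}

    if "fate_calls" in state:
        report = asymmetry_report(dn_table, state["fate_calls"], config.cliff_large)
        rep_path = out_dir / "asymmetry_report.tsv"
        report.to_csv(rep_path, sep="\t", index=False)
        manifest.register("seqdiv", "asymmetry_report", rep_path)


def _stage_duptime(config: RunConfig, out_dir: Path, manifest: RunManifest, state: dict) -> None:
    newick = config.tree_newick or _balanced_newick(
        list(config.pre_species) + list(config.post_species)
    )
    tree = SpeciesTree.from_newick(newick)
    schedules = {}
    rng = np.random.default_rng(config.seed + 303)
    for k in range(config.n_duptime_families):
        schedules[f"cnfam{k:03d}"] = synth.random_event_schedule(
            tree, config.n_events, seed=int(rng.integers(0, 2**31 - 1))
        )
    matrix, truth = synth.simulate_copy_number_matrix(tree, schedules)
    event_maps = duptime_mod.events_for_matrix(tree, matrix)
    rows = []
    for family, emap in event_maps.items():
        replay_ok = bool(
            (duptime_mod.replay_events(tree, emap) == matrix[family]).all()
        )
        for e in emap.events:
            rows.append(
                {
                    "family": family,
                    "branch": e.branch,
                    "kind": e.kind,
                    "multiplicity": e.multiplicity,
                    "primary": e.branch == emap.primary_duplication_branch
                    and e.kind == "dup",
                    "total_cost": emap.total_cost,
                    "replay_ok": replay_ok,
                }
            )
    events_df = pd.DataFrame(
        rows,
        columns=["family", "branch", "kind", "multiplicity", "primary",
                 "total_cost", "replay_ok"],
    )
    ev_path = out_dir / "duplication_events.tsv"
    events_df.to_csv(ev_path, sep="\t", index=False)
    manifest.register("duptime", "events", ev_path)
    json_path = out_dir / "event_maps.json"
    json_path.write_text(
        json.dumps({f: m.to_dict() for f, m in event_maps.items()},
                   indent=2, sort_keys=True)
    )
    manifest.register("duptime", "event_maps", json_path)
    matrix_path = out_dir / "copy_numbers.tsv"
    matrix.to_csv(matrix_path, sep="\t")
    manifest.register("duptime", "copy_numbers", matrix_path)
    manifest.record_counts["duptime"] = {
        "families": len(event_maps),
        "events": int(sum(len(m.events) for m in event_maps.values())),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "metrics": _stage_metrics,
    "classify": _stage_classify,
    "seqdiv": _stage_seqdiv,
    "duptime": _stage_duptime,
}


def asymmetry_report(
    dn_table: pd.DataFrame,
    fate_calls: list,
    cliff_large: float = seqdiv.CLIFF_LARGE_THRESHOLD,
) -> pd.DataFrame:
    """Join per-family sequence asymmetry (Cliff's delta of dN between
    paralogs) with the expression-based fate classification.

    Families are matched by position when the two inputs come from
    parallel simulations (sorted order) and by name when names overlap.
    Reports delta magnitude, the large-effect flag at ``cliff_large``,
    the fate category and the major paralog.
    """
    call_by_family = {c.family: c for c in fate_calls}
    dn_families = sorted(dn_table["family"].unique())
    overlap = [f for f in dn_families if f in call_by_family]
    if not overlap:
        fate_families = sorted(call_by_family)
        if len(fate_families) >= len(dn_families):
            pairing = dict(zip(dn_families, fate_families))
        else:
            logger.warning("family sets disjoint and sizes incompatible; empty report")
            return pd.DataFrame(
                columns=["family", "cliffs_delta", "large_asymmetry",
                         "fate_category", "major_paralog"]
            )
    else:
        pairing = {f: f for f in overlap}
    rows = []
    for dn_family, fate_family in pairing.items():
        call = call_by_family[fate_family]
        sub = dn_table[dn_table["family"] == dn_family]
        dn_a = sub.loc[sub["paralog"] == "A", "dN"].dropna()
        dn_b = sub.loc[sub["paralog"] == "B", "dN"].dropna()
        if dn_a.empty or dn_b.empty:
            continue
        delta = seqdiv.cliffs_delta(dn_b, dn_a)
        rows.append(
            {
                "family": dn_family,
                "cliffs_delta": delta.delta_magnitude,
                "large_asymmetry": delta.delta_magnitude > cliff_large,
                "fate_category": call.category,
                "major_paralog": call.major_paralog,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["family", "cliffs_delta", "large_asymmetry",
                 "fate_category", "major_paralog"],
    )


def demo_config(out_dir: str | Path, seed: int = 0) -> RunConfig:
    """Small bundled configuration exercising every stage."""
    return RunConfig(
        out_dir=str(out_dir),
        seed=seed,
        n_pairs=50,
        n_single_copy_families=150,
        n_stable=50,
        n_perm=1000,
        n_seqdiv_families=10,
        n_codons=300,
        n_duptime_families=5,
    )
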