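"""End-to-end screening pipeline with config validation and manifests.

Stages: simulate -> train -> panel -> fingerprint -> screen -> compare.
Each stage persists its artifact in the run directory and is skipped on
re-invocation when the artifact already exists, so a run can resume
after interruption. A manifest recording the config, package version
and artifact checksums is written next to the outputs; two runs with
the same config and seed produce checksum-identical hits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__, cgbfp, cgbsp_screen, chem_io, cpi_model, synthetic_data

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full configuration of an end-to-end run.

    Defaults carry the method's fixed constants: a panel eligibility
    threshold of 100 positive training pairs per target, a top-40 hit
    list, Morgan radius 2 with 2048 bits for the structural baseline,
    and the 0.5 binding-score positivity rule baked into the model.
    """

    seed: int = 0
    workers: int = 1
    # synthetic universe
    n_targets: int = 20
    n_compounds: int = 2000
    n_scaffolds: int = 8
    family_count: int = 4
    noise_rate: float = 0.05
    min_binders: int = 160
    # training
    holdout_fraction: float = 0.25
    max_pos_per_target: int | None = 120
    kernel: str = "rbf"
    C: float = 10.0
    gamma: float | str = 0.01
    negative_ratio: float = 1.0
    # panel + screen
    panel_min_count: int = 100
    top_k: int = 40
    library_size: int = 5000
    n_references: int = 20
    n_hops: int = 50
    morgan_radius: int = 2
    morgan_bits: int = 2048

    def hyperparams(self) -> cpi_model.Hyperparams:
        return cpi_model.Hyperparams(
            kernel=self.kernel,
            C=self.C,
            gamma=self.gamma,
            negative_ratio=self.negative_ratio,
        )


def validate_config(config: dict | RunConfig | None) -> RunConfig:
    """Normalize a config mapping: inject defaults, check ranges."""
    if config is None:
        config = {}
    if isinstance(config, RunConfig):
        cfg = config
    else:
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(config) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = RunConfig(**config)
    if cfg.panel_min_count < 1:
        raise ValueError(f"panel_min_count must be >= 1, got {cfg.panel_min_count}")
    if cfg.top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {cfg.top_k}")
    if not 0 <= cfg.noise_rate < 0.5:
        raise ValueError(f"noise_rate must be in [0, 0.5), got {cfg.noise_rate}")
    if not 0 <= cfg.holdout_fraction < 1:
        raise ValueError(f"holdout_fraction must be in [0, 1), got {cfg.holdout_fraction}")
    if cfg.workers < 1:
        raise ValueError(f"workers must be >= 1, got {cfg.workers}")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return validate_config(payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_end_to_end(config: RunConfig | dict | None, out_dir: str | Path) -> Path:
    """Run simulate -> train -> panel -> fingerprint -> screen -> compare.

    Returns the run directory. Completed stages (detected by their
    persisted artifact) are not recomputed.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name: str, artifact: Path, fn):
        if artifact.exists():
            logger.info("stage %s: artifact %s exists, skipping", name, artifact.name)
            return
        t0 = time.time()
        fn()
        timings[name] = round(time.time() - t0, 2)
        logger.info("stage %s: %.1fs", name, timings[name])

    # --- simulate ---------------------------------------------------------
    data_dir = out / "data"
    universe = synthetic_data.generate_universe(
        n_targets=cfg.n_targets,
        n_compounds=cfg.n_compounds,
        n_scaffolds=cfg.n_scaffolds,
        family_count=cfg.family_count,
        noise_rate=cfg.noise_rate,
        min_binders=cfg.min_binders,
        seed=cfg.seed,
    )
    stage("simulate", data_dir / "cpi.tsv", lambda: synthetic_data.write_universe(universe, data_dir))

    train_records, test_records = synthetic_data.emit_training_set(
        universe,
        holdout_fraction=cfg.holdout_fraction,
        seed=cfg.seed,
        negative_ratio=cfg.negative_ratio,
        max_pos_per_target=cfg.max_pos_per_target,
    )
    train_path = data_dir / "cpi_train.tsv"
    stage("split", train_path, lambda: chem_io.write_cpi_table(train_records, train_path))

    # --- train ------------------------------------------------------------
    model_path = out / "model.joblib"

    def _train():
        model = cpi_model.train(
            train_records,
            universe.compounds,
            universe.targets,
            hyperparams=cfg.hyperparams(),
            seed=cfg.seed,
        )
        cpi_model.save_model(model, model_path)

    stage("train", model_path, _train)
    model = cpi_model.load_model(model_path)

    # --- panel ------------------------------------------------------------
    panel_path = out / "panel.tsv"
    stage(
        "panel",
        panel_path,
        lambda: cgbfp.save_panel(
            cgbfp.build_panel(train_records, min_count=cfg.panel_min_count), panel_path
        ),
    )
    panel = cgbfp.load_panel(panel_path)

    # --- benchmark library + fingerprints ---------------------------------
    bench = synthetic_data.make_scaffold_hop_benchmark(
        universe,
        seed=cfg.seed,
        library_size=cfg.library_size,
        n_hops=cfg.n_hops,
        n_references=cfg.n_references,
    )
    refs_path = data_dir / "references.smi"
    stage("references", refs_path, lambda: chem_io.write_molecules(bench.references, refs_path))
    lib_path = data_dir / "screening_library.smi"
    stage("library", lib_path, lambda: chem_io.write_molecules(bench.library, lib_path))

    fp_path = out / "library_fp.csv"
    stage(
        "fingerprint",
        fp_path,
        lambda: chem_io.save_matrix(
            cgbfp.fingerprint_batch(
                model, bench.library, panel, universe.targets, n_workers=cfg.workers
            ),
            fp_path,
        ),
    )

    # --- screen -----------------------------------------------------------
    hits_path = out / "hits.tsv"

    def _screen():
        library_fp = chem_io.load_matrix(fp_path)
        ref_fp = cgbfp.fingerprint_batch(model, bench.references, panel, universe.targets)
        refs = [
            cgbfp.CGBFP(cid, panel, ref_fp.values[i]) for i, cid in enumerate(ref_fp.row_ids)
        ]
        hits = cgbsp_screen.rank_library(library_fp, refs, top_k=cfg.top_k)
        cgbsp_screen.write_hits(hits, hits_path)

    stage("screen", hits_path, _screen)

    # --- compare top hit against its nearest reference ---------------------
    compare_path = out / "top_hit_comparison.tsv"

    def _compare():
        library_fp = chem_io.load_matrix(fp_path)
        ref_fp = cgbfp.fingerprint_batch(model, bench.references, panel, universe.targets)
        lines = Path(hits_path).read_text().splitlines()[1:]
        by_id = {c.id: c for c in bench.library}
        ref_by_id = {c.id: c for c in bench.references}
        with open(compare_path, "w") as fh:
            fh.write("hit_id\treference_id\tcgbsp_score\tmorgan_tanimoto\n")
            for ln in lines[:5]:
                _, hit_id, _, ref_id = ln.split("\t")
                hfp = cgbfp.CGBFP(hit_id, panel, library_fp.row(hit_id))
                rfp = cgbfp.CGBFP(
                    ref_id, panel, ref_fp.values[ref_fp.row_ids.index(ref_id)]
                )
                cmp_ = cgbsp_screen.compare_profiles(
                    by_id[hit_id], hfp, ref_by_id[ref_id], rfp,
                    radius=cfg.morgan_radius, n_bits=cfg.morgan_bits,
                )
                fh.write(
                    f"{cmp_.hit_id}\t{cmp_.reference_id}\t"
                    f"{cmp_.cgbsp_score:.6f}\t{cmp_.morgan_tanimoto:.6f}\n"
                )

    stage("compare", compare_path, _compare)

    # --- manifest ----------------------------------------------------------
    artifacts = {
        p.relative_to(out).as_posix(): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "tool_version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": _config_hash(cfg),
        "stage_seconds": timings,
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
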