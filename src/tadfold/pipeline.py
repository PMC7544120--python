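"""Configuration and end-to-end orchestration.

One YAML config drives the whole analysis: simulate the two polymer
ensembles, synthesize the imaging-like two-population dataset, preprocess to
contact vectors, train the embedding (2-latent) and probability (25-latent)
VAEs, fit the folding coordinate, and compute energy profiles and structural
statistics.  A single global seed fans out to per-stage seeds via CRC32 of
the stage name, so any stage can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import energetics, folding_coordinate, imaging_synth, polymer_sim, preprocess
from . import structure_stats, vae

logger = logging.getLogger("tadfold")

__all__ = ["RunConfig", "validate_config", "stage_seed", "run_pipeline", "STAGES"]

STAGES = ["simulate", "synth", "preprocess", "train", "coordinate", "energetics", "stats"]

# scale presets: full study conditions vs. a desk-scale run for laptops/CI
_PRESETS = {
    "full": dict(n_steps=50_000_000, save_every=500, epochs=1000, epochs_embed=1000,
                  n_cells_per_type=10_000),
    "desk": dict(n_steps=100_000, save_every=100, epochs=60, epochs_embed=60,
                 n_cells_per_type=400),
}


@dataclass
class RunConfig:
    seed: int
    outdir: str
    preset: str = "desk"
    n_steps: int | None = None
    save_every: int | None = None
    epochs: int | None = None
    epochs_embed: int | None = None
    n_cells_per_type: int | None = None
    cutoff_nm: float = 450.0
    nm_per_sigma: float = 150.0
    noise_sd: float = 30.0
    missing_prob: float = 0.1
    mixture_weights: tuple[float, float] = (0.85, 0.15)
    latent_embed: int = 2
    latent_prob: int = 25
    polymer: polymer_sim.PolymerModelParams = field(
        default_factory=polymer_sim.PolymerModelParams
    )

    def __post_init__(self) -> None:
        if self.preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        for k, v in _PRESETS[self.preset].items():
            if getattr(self, k) is None:
                setattr(self, k, v)
        if abs(self.cutoff_nm - self.nm_per_sigma * self.polymer.contact_cutoff) > 1e-6:
            logger.warning(
                "cutoff_nm (%s) != nm_per_sigma * contact_cutoff (%s): the imaging and "
                "simulation pipelines use inconsistent contact definitions",
                self.cutoff_nm, self.nm_per_sigma * self.polymer.contact_cutoff,
            )


def validate_config(path) -> RunConfig:
    """Parse a YAML config, fill preset defaults, check cross-stage consistency."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("config is missing required field: seed")
    if "outdir" not in raw:
        raise ValueError("config is missing required field: outdir")
    poly = raw.pop("polymer", {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    if "mixture_weights" in raw:
        raw["mixture_weights"] = tuple(raw["mixture_weights"])
    return RunConfig(polymer=polymer_sim.PolymerModelParams(**poly), **raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Documented fan-out: CRC32(stage name) XOR global seed, modulo 2^31."""
    return (zlib.crc32(stage.encode()) ^ int(global_seed)) % (2**31)


def _hash_file(path: Path) -> str:
    """Content hash; npz archives are hashed by member arrays (zip headers
    embed timestamps and would defeat rerun-determinism checks)."""
    h = hashlib.sha256()
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            for name in sorted(data.files):
                h.update(name.encode())
                h.update(np.ascontiguousarray(data[name]).tobytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in order and write a JSON manifest.

    Each stage reads the previous stage's artifacts from ``cfg.outdir``;
    requesting a stage whose inputs are absent raises an error naming the
    stage to run first.
    """
    stages = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {
        "config": dataclasses.asdict(cfg), "artifacts": {}}
    art = manifest["artifacts"]

    def need(name: str, producer: str) -> Path:
        p = out / name
        if not p.exists():
            raise FileNotFoundError(
                f"missing artifact {name}; run stage '{producer}' first")
        return p

    for stage in stages:
        logger.info("stage %s", stage)
        seed = stage_seed(cfg.seed, stage)
        if stage == "simulate":
            for tag, chrom in (("reference", False), ("chromatin", True)):
                traj = polymer_sim.run_langevin(
                    cfg.polymer, cfg.n_steps, cfg.save_every,
                    seed=stage_seed(seed, tag), chromatin_like=chrom)
                np.save(out / f"traj_{tag}.npy", traj)
                art[f"traj_{tag}.npy"] = _hash_file(out / f"traj_{tag}.npy")
        elif stage == "synth":
            ref = np.load(need("traj_reference.npy", "simulate"))
            chrom = np.load(need("traj_chromatin.npy", "simulate"))
            scfg = imaging_synth.SynthConfig(
                nm_per_sigma=cfg.nm_per_sigma, noise_sd=cfg.noise_sd,
                missing_prob=cfg.missing_prob, n_cells_per_type=cfg.n_cells_per_type,
                mixture_weights=cfg.mixture_weights, seed=seed)
            cells = imaging_synth.generate_dataset(ref, chrom, scfg)
            imaging_synth.write_traces(cells, out / "traces.tsv")
            art["traces.tsv"] = _hash_file(out / "traces.tsv")
        elif stage == "preprocess":
            cells = imaging_synth.read_traces(need("traces.tsv", "synth"))
            X, labels = preprocess.traces_to_feature_matrix(
                cells, cutoff_nm=cfg.cutoff_nm, seed=seed)
            np.savez(out / "qdata.npz", X=X, labels=np.asarray(labels))
            art["qdata.npz"] = _hash_file(out / "qdata.npz")
        elif stage == "train":
            data = np.load(need("qdata.npz", "preprocess"))
            X, labels = data["X"], data["labels"]
            arch = vae.VAEArchitecture(input_dim=X.shape[1], latent_dim=cfg.latent_embed)
            model = vae.train_vae(X, arch, vae.TrainConfig(
                epochs=cfg.epochs_embed, seed=stage_seed(seed, "embed")))
            vae.save_model(model, out / "model_embed.npz")
            for tag, lab in (("wt", "WT"), ("depleted", "depleted")):
                Xs = X[labels == lab]
                archp = vae.VAEArchitecture(input_dim=X.shape[1], latent_dim=cfg.latent_prob)
                mp = vae.train_vae(Xs, archp, vae.TrainConfig(
                    epochs=cfg.epochs, seed=stage_seed(seed, tag)))
                vae.save_model(mp, out / f"model_{tag}.npz")
            for f in ("model_embed.npz", "model_wt.npz", "model_depleted.npz"):
                art[f] = _hash_file(out / f)
        elif stage == "coordinate":
            data = np.load(need("qdata.npz", "preprocess"))
            X, labels = data["X"], data["labels"]
            model = vae.load_model(need("model_embed.npz", "train"))
            mu, _ = vae.encode(model, X)
            sep = folding_coordinate.fit_separator(mu[labels == "WT"],
                                                   mu[labels == "depleted"])
            coords = folding_coordinate.coordinate_value(sep, mu)
            import pandas as pd

            pd.DataFrame({
                "label": labels, "z1": mu[:, 0], "z2": mu[:, 1], "coordinate": coords,
            }).to_csv(out / "coords.tsv", sep="\t", index=False)
            np.savez(out / "separator.npz", w=sep.w, b=sep.b)
            art["coords.tsv"] = _hash_file(out / "coords.tsv")
            art["separator.npz"] = _hash_file(out / "separator.npz")
        elif stage == "energetics":
            data = np.load(need("qdata.npz", "preprocess"))
            X = data["X"]
            import pandas as pd

            coords = pd.read_csv(need("coords.tsv", "coordinate"), sep="\t")[
                "coordinate"].to_numpy()
            m_wt = vae.load_model(need("model_wt.npz", "train"))
            m_dep = vae.load_model(need("model_depleted.npz", "train"))
            logp = vae.estimate_log_prob_batch(m_wt, X, n_samples=20, seed=seed)
            du = energetics.interaction_energy_batch(m_wt, m_dep, X, seed=seed)
            prof_f = energetics.profile_along_coordinate(-logp, coords)
            prof_u = energetics.profile_along_coordinate(du, coords)
            for name, prof in (("free_energy", prof_f), ("interaction_energy", prof_u)):
                pd.DataFrame({"bin_center": prof.centers, "mean": prof.mean,
                              "sd": prof.sd, "n": prof.count}).to_csv(
                    out / f"profile_{name}.tsv", sep="\t", index=False)
                art[f"profile_{name}.tsv"] = _hash_file(out / f"profile_{name}.tsv")
        elif stage == "stats":
            data = np.load(need("qdata.npz", "preprocess"))
            X = data["X"]
            cells = imaging_synth.read_traces(need("traces.tsv", "synth"))
            mmap = structure_stats.mean_distance_map(
                [c for c in cells if c.label == "WT"])
            prof = structure_stats.boundary_score_profile(mmap)
            np.savetxt(out / "mean_distance_map.tsv", mmap, delimiter="\t")
            np.savetxt(out / "boundary_scores.tsv", prof.scores, delimiter="\t")
            mom = structure_stats.contact_moments(X, seed=seed)
            np.savez(out / "moments.npz", first=mom.first, second=mom.second,
                     independent=mom.independent, pairs=mom.pair_indices)
            for f in ("mean_distance_map.tsv", "boundary_scores.tsv", "moments.npz"):
                art[f] = _hash_file(out / f)
        manifest["artifacts"] = art
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
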