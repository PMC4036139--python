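"""End-to-end pipeline: simulate -> kinematics -> cluster -> chains ->
SPM mining -> spatial/electromotor analytics -> report bundle.

Every stage persists its intermediate under the output directory and the
summary embeds the configuration hash and master seed, so a bundle is
reproducible from its embedded configuration alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import chains as chains_mod
from . import clustering, io, kinematics, spatial, spm
from .config import ConfigError, GeneratorConfig
from .simulate import generate_dataset

logger = logging.getLogger(__name__)

_RUN_FIELDS = None


@dataclass
class RunConfig:
    """All stage parameters with their standard defaults."""

    out_dir: str = "electrokin_run"
    seed: int = 0
    n_sessions_object: int = 3
    n_sessions_no_object: int = 2
    n_frames_per_session: int = 10_000
    k_min: int = 2
    k_max: int = 50
    n_replicates: int = 20
    fixed_k: Optional[int] = None
    min_chain_len: int = 10
    thrust_threshold: float = -2.0
    n_transitions: int = 5
    top_n: int = 100
    d_max_cm: float = 4.0
    bin_cm: float = 1.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the summary dict.

    Any stage failure aborts with the stage name in the raised error.
    Identical seeds give identical bundles.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        params = {k: v for k, v in asdict(config).items() if k != "out_dir"}
        summary: dict = {"seed": config.seed, "config_hash": io.config_hash(params)}
        gen = GeneratorConfig(n_frames_target=config.n_frames_per_session)

        stage = "simulate"
        obj_sessions = generate_dataset(gen, config.n_sessions_object, seed=config.seed)
        noobj_sessions = generate_dataset(
            gen.replace(object_present=False),
            config.n_sessions_no_object, seed=config.seed + 50_000,
        )
        for i, s in enumerate(noobj_sessions):
            s.session_id = f"S{config.n_sessions_object + i:02d}"
        sessions = obj_sessions + noobj_sessions
        io.write_session_tsv(sessions, out / "sessions.tsv")

        stage = "kinematics"
        kins = [kinematics.compute_kinematics(s) for s in sessions]
        scaler = kinematics.fit_scaler(kins)
        zs = [kinematics.apply_scaler(scaler, k) for k in kins]

        stage = "cluster"
        z_all = np.concatenate(zs)
        model = clustering.fit_pm_model(
            z_all, scaler, k=config.fixed_k, seed=config.seed,
            kscan_kwargs={"k_range": range(config.k_min, config.k_max + 1),
                          "n_replicates": config.n_replicates},
        )
        (out / "pm_model.json").write_text(model.to_json())
        labels = [clustering.assign(model, z) for z in zs]
        for k, lab, z in zip(kins, labels, zs):
            io.write_kinematics_tsv(k, out / f"kinematics_{k.session_id}.tsv", labels=lab, z=z)

        stage = "chains"
        all_chains = []
        for k, lab in zip(kins, labels):
            all_chains += chains_mod.extract_chains(k, lab, pm_id=1, min_len=config.min_chain_len)
        all_chains = chains_mod.split_pm01(all_chains, threshold=config.thrust_threshold)
        io.write_chains_tsv(all_chains, out / "chains.tsv")
        stationary = [c for c in all_chains if c.behavior == "stationary"]
        backwards = [c for c in all_chains if c.behavior == "backwards"]

        stage = "spms"
        obj_idx = [i for i, s in enumerate(sessions) if s.condition == "object"]
        noobj_idx = [i for i, s in enumerate(sessions) if s.condition == "no_object"]
        token_seqs = []
        for i in obj_idx:
            for seg in np.unique(kins[i].segment):
                toks, _ = spm.collapse_runs(labels[i][kins[i].segment == seg])
                token_seqs.append(toks)
        model_tr = spm.transition_matrix(token_seqs)
        ranked = spm.enumerate_top_spms(model_tr, config.n_transitions, config.top_n)
        catalog = spm.reduce_spms(ranked, model.mirror_pairs, config.n_transitions)
        contrast = spm.condition_contrast(
            catalog, [labels[i] for i in noobj_idx], [labels[i] for i in obj_idx]
        )
        (out / "spm_catalog.json").write_text(catalog.to_json())
        contrast.to_csv(out / "spm_contrast.tsv", sep="\t", index=False)

        stage = "spatial"
        approach_entry = catalog.entries[int(contrast["diff"].idxmax())]
        n_approach = 0
        for i in obj_idx:
            pos = sessions[i].locate(kins[i].frame_index)
            d = spatial.object_distance(sessions[i].x[pos], sessions[i].y[pos])
            occ = spm.match_occurrences(labels[i], approach_entry, catalog.mirror_pairs)
            n_approach += len(spatial.approach_filter(occ, d, d_max=config.d_max_cm))

        stage = "report"
        summary.update(
            {
                "selected_k": int(model.selected_k),
                "pm_table": model.centroids_raw.round(3).tolist(),
                "mirror_pairs": [list(p) for p in model.mirror_pairs],
                "chains": {
                    "stationary": chains_mod.chain_statistics(stationary),
                    "backwards": chains_mod.chain_statistics(backwards),
                },
                "spm_catalog_size": catalog.size,
                "n_raw_spms": catalog.n_raw_sequences,
                "approach_chain_count": int(n_approach),
            }
        )
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
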