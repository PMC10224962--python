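"""End-to-end orchestration: synthesize/load -> extract -> repertoire -> valence.

A single master seed deterministically spawns per-stage seeds (synthesis,
permutation) so stages can be re-run independently; outputs carry the
config and seed and are byte-identical across repeated runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import acoustics, audio_io, repertoire, synth, valence

__all__ = ["PipelineConfig", "run_pipeline", "extract_table"]

log = logging.getLogger("dovekie")

MODES = ("synthetic_waveform", "synthetic_features", "real_audio")


@dataclass
class PipelineConfig:
    mode: str = "synthetic_features"
    n_per_type: int = 30
    seed: int = 0
    n_permutations: int = 1000
    output_dir: str = "dovekie_out"
    annotations: str | None = None  # CSV path, real_audio mode only
    audio_dir: str | None = None
    pitch_floor: float = acoustics.DEFAULT_F0_FLOOR
    pitch_ceiling: float = acoustics.DEFAULT_F0_CEILING
    frame_s: float = acoustics.DEFAULT_FRAME_S
    hop_s: float = acoustics.DEFAULT_HOP_S
    voicing_threshold: float = acoustics.DEFAULT_VOICING_THRESHOLD
    leak_free_cv: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_per_type < 1:
            raise ValueError("n_per_type must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.mode == "real_audio" and not self.annotations:
            raise ValueError("real_audio mode requires an annotations CSV")


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed).spawn(2)
    return {"synthesis": int(ss[0].generate_state(1)[0] % 2**31),
            "permutation": int(ss[1].generate_state(1)[0] % 2**31)}


def extract_table(records: list[audio_io.CallRecord],
                  config: PipelineConfig) -> pd.DataFrame:
    """Feature-extract a list of call records into a tidy table."""
    rows = []
    for rec in records:
        log.debug("extracting %s", rec.call_id)
        fv = acoustics.extract_features(
            rec.waveform, rec.sample_rate, call_id=rec.call_id,
            call_type=rec.call_type, context=rec.context,
            floor=config.pitch_floor, ceiling=config.pitch_ceiling,
            frame=config.frame_s, hop=config.hop_s,
            voicing_threshold=config.voicing_threshold)
        row = {"call_id": rec.call_id, "call_type": rec.call_type,
               "context": rec.context}
        row.update(fv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def _build_feature_table(config: PipelineConfig,
                         seeds: dict[str, int]) -> pd.DataFrame:
    specs = synth.default_specs()
    if config.mode == "synthetic_features":
        return synth.sample_feature_table(specs, config.n_per_type,
                                          seed=seeds["synthesis"])
    if config.mode == "synthetic_waveform":
        corpus = synth.synthesize_corpus(specs, config.n_per_type,
                                         seed=seeds["synthesis"])
        records = [audio_io.CallRecord(call_id=c.call_id, call_type=c.call_type,
                                       waveform=c.waveform,
                                       sample_rate=c.sample_rate)
                   for c in corpus.calls]
        return extract_table(records, config)
    ann = pd.read_csv(config.annotations)
    audio_dir = Path(config.audio_dir or Path(config.annotations).parent)
    records = []
    for _, row in ann.iterrows():
        rec = audio_io.read_call(audio_dir / row["wav_path"], row)
        records.append(rec)
    records = audio_io.select_calls(records, n_per_type=config.n_per_type)
    return extract_table(records, config)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write all reports under ``output_dir``.

    Outputs: ``features.csv`` (per-call parameters), ``summary.csv``
    (per-type mean/SD), ``repertoire.json`` (eigenvalues, retained
    components, observed LOO-CCR, permutation null), ``valence_models.csv``
    and ``valence.json`` (MANOVA + linear models), and ``manifest.json``
    (config, seeds, version).  Returns the combined report as a dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    log.info("stage 1/4: building feature table (%s)", config.mode)
    table = _build_feature_table(config, seeds)
    table = repertoire.canonicalize(table)
    table = valence.add_valence(table)
    table.to_csv(out / "features.csv", index=False)

    log.info("stage 2/4: per-type summary")
    summary = repertoire.summarize(table)
    summary.to_csv(out / "summary.csv")

    log.info("stage 3/4: repertoire discrimination (%d permutations)",
             config.n_permutations)
    model = repertoire.fit_pca(table)
    perm = repertoire.permutation_test(
        table, n_permutations=config.n_permutations,
        seed=seeds["permutation"], leak_free=config.leak_free_cv)
    rep_report = {
        "eigenvalues": [float(v) for v in model.eigenvalues],
        "n_retained": int(len(model.retained)),
        "observed_ccr": perm.observed_ccr,
        "chance_expectation": perm.chance_expectation,
        "p_value": perm.p_value,
        "n_permutations": perm.n_permutations,
    }

    log.info("stage 4/4: valence analysis")
    vtable = valence.valence_subset(table)
    pcs = repertoire.pc_scores(model, vtable, n_components=5)
    manova = valence.manova_on_pcs(pcs, vtable["valence"], vtable["call_type"])
    models = valence.fit_valence_models(vtable)
    valence.valence_report(models).to_csv(out / "valence_models.csv",
                                          index=False)
    val_report = {
        "n_obs": int(len(vtable)),
        "manova": manova.summary(),
        "models": [dataclasses.asdict(m) for m in models],
    }

    report = {
        "config": asdict(config),
        "seeds": seeds,
        "version": __version__,
        "n_calls": int(len(table)),
        "repertoire": rep_report,
        "valence": val_report,
    }
    (out / "repertoire.json").write_text(json.dumps(rep_report, indent=2,
                                                    sort_keys=True))
    (out / "valence.json").write_text(json.dumps(val_report, indent=2,
                                                 sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(
        {"config": asdict(config), "seeds": seeds, "version": __version__},
        indent=2, sort_keys=True))
    return report
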