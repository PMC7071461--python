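"""End-to-end stage drivers shared by the CLI and the scripts."""

from __future__ import annotations

import logging
from pathlib import Path

from . import io
from .evaluate import EpochClassificationExperiment
from .preprocess import epoch as cut_epochs
from .preprocess import bandpass_notch, preprocess_recording
from .spectral import build_feature_table
from .synthetic import generate_cohort

log = logging.getLogger("pnespipe")


def simulate_cohort(config, outdir=None):
    """Generate the synthetic cohort and write recordings + manifest."""
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    recordings = generate_cohort(
        config.cnt_profile, config.pnes_profile, config.cohort)
    entries = []
    for rec in recordings:
        if config.write_edf:
            path = outdir / f"{rec.subject_id}.edf"
            io.write_edf(rec, path)
        else:
            path = outdir / f"{rec.subject_id}.csv"
            io.write_ascii_eeg(rec, path)
        entries.append({
            "subject_id": rec.subject_id,
            "class_label": rec.class_label,
            "path": path.name,
            "fs": rec.fs,
        })
        log.info("wrote %s: %d ch x %d samples", path.name,
                 rec.n_channels, rec.n_samples)
    manifest = io.write_manifest(entries, outdir / "manifest.json")
    log.info("manifest: %s (%d subjects, seed=%d)", manifest, len(entries),
             config.cohort.seed)
    return manifest


def extract_features(manifest_path, config, annotations=None):
    """Read a cohort manifest and build the feature table.

    ``annotations`` optionally maps subject_id -> ArtifactAnnotation.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    epoch_sets = []
    for entry in io.read_manifest(manifest_path):
        path = base / entry["path"]
        if not path.exists():
            raise FileNotFoundError(
                f"missing recording for subject {entry['subject_id']}: {path}")
        if path.suffix.lower() == ".edf":
            rec = io.read_edf(path)
        else:
            rec = io.read_ascii_eeg(path, fs=entry["fs"])
        rec = rec.replace(subject_id=entry["subject_id"],
                          class_label=entry["class_label"])
        ann = (annotations or {}).get(entry["subject_id"])
        es = preprocess_recording(
            rec, filter_spec=config.filter, target_fs=config.cohort.fs,
            annotation=ann, epoch_len_s=config.cohort.epoch_len_s,
            max_epochs=config.cohort.n_epochs)
        log.info("subject %s: %d epochs x %d ch x %d samples "
                 "(%d features/subject)", es.subject_id, es.n_epochs,
                 es.n_channels, es.epoch_samples,
                 es.n_epochs * es.n_channels * len(config.bands) * 4)
        epoch_sets.append(es)
    table = build_feature_table(epoch_sets, config.welch, config.bands)
    log.info("feature table: %d epochs x %d features", len(table),
             table.shape[1] - 3)
    return table


def cohort_feature_table(config, preprocess=True):
    """In-memory simulate -> (optionally filter) -> epoch -> features."""
    recordings = generate_cohort(
        config.cnt_profile, config.pnes_profile, config.cohort)
    epoch_sets = []
    for rec in recordings:
        if preprocess:
            rec = bandpass_notch(rec, config.filter)
        epoch_sets.append(cut_epochs(rec, config.cohort.epoch_len_s,
                                     max_epochs=config.cohort.n_epochs))
    return build_feature_table(epoch_sets, config.welch, config.bands)


def evaluate_table(table, config):
    """Run the classifier x scheme grid on a feature table."""
    exp = EpochClassificationExperiment(
        table,
        classifiers=config.classifiers,
        schemes=config.schemes,
        train_per_class=config.train_per_class,
        n_random_splits=config.n_random_splits,
        standardize=config.standardize,
        epoch_level=config.epoch_level_split,
        seed=config.seed,
    )
    return exp.fit()
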