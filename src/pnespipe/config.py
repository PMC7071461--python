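"""Pipeline configuration: one serialisable object per run.

Every pipeline constant (band edges, filter corners, Welch geometry, epoch
length, cohort size, classifier parameters, split sizes) is a named default
here, so a run is reproducible from the config file plus the seed alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .evaluate import ClassifierSpec
from .preprocess import FilterSpec
from .spectral import DEFAULT_BANDS, BandDefinition, WelchConfig
from .synthetic import ClassSpectralProfile, CohortSpec, default_profiles


@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    cnt_profile: ClassSpectralProfile = None
    pnes_profile: ClassSpectralProfile = None
    filter: FilterSpec = field(default_factory=FilterSpec)
    welch: WelchConfig = field(default_factory=WelchConfig)
    bands: tuple = DEFAULT_BANDS
    classifiers: tuple = (
        ClassifierSpec("SVM"), ClassifierSpec("LDA"), ClassifierSpec("NB"))
    schemes: tuple = ("random_split", "loo")
    train_per_class: int = 7
    n_random_splits: int = 1
    standardize: bool = True
    epoch_level_split: bool = False
    seed: int = 0
    outdir: str = "pnespipe_out"
    write_edf: bool = False

    def __post_init__(self):
        if self.cnt_profile is None or self.pnes_profile is None:
            cnt, pnes = default_profiles()
            self.cnt_profile = self.cnt_profile or cnt
            self.pnes_profile = self.pnes_profile or pnes

    # -- serialisation ------------------------------------------------------

    def to_dict(self):
        doc = asdict(self)
        doc["bands"] = [asdict(b) for b in self.bands]
        doc["classifiers"] = [asdict(c) for c in self.classifiers]
        doc["schemes"] = list(self.schemes)
        return doc

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    @classmethod
    def from_dict(cls, doc):
        doc = dict(doc)
        doc["cohort"] = CohortSpec(**doc.get("cohort", {}))
        if doc.get("cnt_profile"):
            doc["cnt_profile"] = ClassSpectralProfile(**doc["cnt_profile"])
        if doc.get("pnes_profile"):
            doc["pnes_profile"] = ClassSpectralProfile(**doc["pnes_profile"])
        doc["filter"] = FilterSpec(**doc.get("filter", {}))
        doc["welch"] = WelchConfig(**doc.get("welch", {}))
        if "bands" in doc:
            doc["bands"] = tuple(BandDefinition(**b) for b in doc["bands"])
        if "classifiers" in doc:
            doc["classifiers"] = tuple(
                ClassifierSpec(**c) for c in doc["classifiers"])
        if "schemes" in doc:
            doc["schemes"] = tuple(doc["schemes"])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
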