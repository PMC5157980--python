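"""Pipeline configuration: every QC threshold default is the published one.

Defaults: variant missingness 0.02, platform Fisher 1e-100, MAF 0.05,
HWE 1e-50, sample missingness 0.05, relatedness 0.0625, 20 PCs at 3 SD,
phenotype outliers at +/-3 SD, minimum ethnicity group 1000, C+T
thresholds 5e-8..1, extrapolation target n = 500,000, 10 CV folds.
Configs round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .gwas_ct import DEFAULT_THRESHOLDS
from .simdata import SyntheticCohortConfig, TraitArchitecture


def _plain(obj):
    """Recursively convert tuples/arrays/numpy scalars to YAML-safe types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class PipelineConfig:
    sim: SyntheticCohortConfig
    variant_max_missing: float = 0.02
    platform_log10p: float = -100.0
    min_maf: float = 0.05
    hwe_log10p: float = -50.0
    sample_max_missing: float = 0.05
    het_sd: float = 3.0
    relatedness_threshold: float = 0.0625
    n_pcs: int = 20
    pca_z: float = 3.0
    phenotype_z: float = 3.0
    min_group_size: int = 1000
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.2
    clump_r2: float = 0.05
    clump_window_bp: int = 1_000_000
    thresholds: tuple = DEFAULT_THRESHOLDS
    cv_folds: int = 10
    holdout_fraction: float = 0.1
    subsample_fractions: tuple = (0.25, 0.4, 0.55, 0.75, 1.0)
    subsample_seeds: int = 2
    rare_min_maf: float = 0.001
    n_target: int = 500_000
    run_two_component: bool = True
    run_maf_stratified: bool = True
    run_multivariate: bool = True
    seed: int = 0

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return _plain(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("sim"))
        sim["trait_architectures"] = [
            a if isinstance(a, TraitArchitecture) else TraitArchitecture(**a)
            for a in sim["trait_architectures"]]
        for key in ("platform_missing_rates", "age_range"):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        for arch in sim["trait_architectures"]:
            arch.maf_bin_edges = tuple(arch.maf_bin_edges)
            arch.maf_bin_variances = tuple(arch.maf_bin_variances)
        for key in ("sex_effects", "age_effects"):
            if key in sim:
                sim[key] = tuple(sim[key])
        cfg = cls(sim=SyntheticCohortConfig(**sim), **d)
        cfg.thresholds = tuple(cfg.thresholds)
        cfg.subsample_fractions = tuple(cfg.subsample_fractions)
        return cfg

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if isinstance(source, Path) or (isinstance(source, str)
                                        and "\n" not in source
                                        and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = source
        return cls.from_dict(yaml.safe_load(text))


def packaged_config(name: str = "small") -> PipelineConfig:
    """Load a configuration shipped with the package (``small`` by default)."""
    text = resources.files("snpblup").joinpath(f"configs/{name}.yaml").read_text()
    return PipelineConfig.from_yaml(text)
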