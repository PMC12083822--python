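"""Run configuration: defaults, YAML loading with strict key validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    """Parameters for the end-to-end driver.

    Every stage parameter defaults to the documented module default. Input
    paths left as None are filled by the synthetic generators. Unknown keys
    in a YAML file are rejected.
    """

    outdir: str = "epidrugscreen_run"
    seed: int = 0

    # stage toggles
    run_screen: bool = True
    run_rank: bool = True
    run_ic50: bool = True
    run_express: bool = True
    run_overlap: bool = True
    run_coexpr: bool = True
    run_atac: bool = True

    # optional user inputs (None -> simulate)
    viability_screen_csv: str | None = None
    viability_panel_csv: str | None = None
    counts_tsv: str | None = None
    samples_tsv: str | None = None
    control_bed: str | None = None
    treated_bed: str | None = None
    tss_bed: str | None = None

    # screen / ranking
    early_day: float = 3.0
    late_day: float = 28.0
    panel_day: float = 7.0
    reference_class: str = "auto"
    top_k: int = 12

    # expression
    normalize_method: str = "median_of_ratios_log2"
    pseudocount: float = 1.0
    fc_threshold: float = 2.0
    n_pcs: int = 2
    min_fraction_consistent: float = 0.75
    min_fraction_universal: float = 1.0

    # coexpr
    min_module_size: int = 30
    fit_cut: float = 0.8
    hub_gene: str | None = None
    hub_k: int = 20

    # atac
    min_reciprocal_overlap: float = 0.5
    link_window: int = 50_000
    min_abs_log2: float = 1.0

    # synthetic scale
    n_genes: int = 1400
    dispersion: float = 0.1
    noise_sd: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ParameterError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ParameterError(f"{path}: unknown config keys {unknown}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
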