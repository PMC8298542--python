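"""Pipeline configuration.

A single flat dataclass holds every tunable of the pipeline: detection
thresholds, segmentation controls, cohort screens and survival-model
settings.  Values can be loaded from an INI-style file (sections are
cosmetic; keys must be globally unique) and overridden per-field.  Every
key is echoed verbatim into the run manifest so a run can be reproduced
from its artifacts alone.
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    # --- event calling -------------------------------------------------
    min_length_bp: int = 2_000_000       # minimum aberration size retained
    min_het: int = 10                    # minimum AB-probe support per call
    min_snps_lrr_only: int = 30          # probe support for LRR-only loss calls
    delta_min: float = 0.05              # minimum mean |BAF-0.5| to call allelic imbalance
    lambda_neutral: float = 0.05         # |median LRR| bound for copy-neutral calls
    lambda_gain: float = 0.05            # median LRR floor for gains
    lambda_loss: float = 0.10            # -median LRR floor for losses

    # --- segmentation --------------------------------------------------
    seg_alpha: float = 0.01
    seg_min_points: int = 10
    seg_permutations: int = 1000

    # --- signal processing --------------------------------------------
    gc_method: str = "lowess"            # "lowess" | "linear"
    gc_window: int = 1001                # probes per smoothing window

    # --- cohort screens ------------------------------------------------
    min_patients: int = 10               # region eligibility (full cohort)
    screen_per_stratum: bool = False     # apply the >=min_patients screen within stratum

    # --- survival ------------------------------------------------------
    p_enter: float = 0.25
    p_stay: float = 0.15
    screen_alpha: float = 0.05
    alpha_ph: float = 0.05
    ties: str = "efron"
    covariate_mode: str = "stepwise"     # "stepwise" | "fixed"
    univariate_screen: str = "logrank"   # "logrank" | "cox"

    # --- run -----------------------------------------------------------
    seed: int = 0
    out_dir: str = "mcascreen_run"
    signal_dir: str = ""
    clinical_path: str = ""
    arm_map_path: str = ""

    def __post_init__(self) -> None:
        if self.p_stay > self.p_enter:
            raise ValueError("p_stay must be <= p_enter")
        for name in ("min_length_bp", "min_het", "delta_min", "lambda_neutral",
                     "lambda_gain", "lambda_loss", "seg_alpha", "seg_min_points",
                     "seg_permutations", "min_patients", "p_enter", "p_stay",
                     "screen_alpha", "alpha_ph"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ties != "efron":
            raise ValueError("only the Efron tie-handling method is supported")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat key=value file with optional [sections]."""
        parser = configparser.ConfigParser()
        text = Path(path).read_text()
        if not text.lstrip().startswith("["):
            text = "[run]\n" + text
        parser.read_string(text)
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kw: dict = {}
        for section in parser.sections():
            for key, raw in parser.items(section):
                if key not in fields:
                    raise KeyError(f"unknown config key: {key}")
                typ = fields[key].type
                if typ in ("int", int):
                    kw[key] = int(float(raw))
                elif typ in ("float", float):
                    kw[key] = float(raw)
                elif typ in ("bool", bool):
                    kw[key] = raw.strip().lower() in ("1", "true", "yes")
                else:
                    kw[key] = raw.strip()
        return cls(**kw)
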