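"""Run configuration: one schema-validated record driving the pipeline.

Unknown keys are rejected so that a typo in a config file fails loudly
instead of silently running defaults.
"""

from __future__ import annotations

from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

__all__ = ["OpticsConfig", "LineageConfig", "AnalysisConfig", "RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticsConfig(_Strict):
    frame_shape: tuple[int, int] = (128, 192)
    vignette: float = Field(0.25, ge=0, lt=1)
    camera_offset: float = Field(100.0, ge=0)
    read_noise_sd: float = Field(5.0, ge=0)
    photons_per_nM: float = Field(10.0, gt=0)
    autofluorescence_nM_equiv: float = Field(15.0, ge=0)


class LineageConfig(_Strict):
    c0_nM: float = Field(92.0, ge=0)
    f1: float = Field(0.58, gt=0, lt=1)
    f2: float = Field(0.57, gt=0, lt=1)
    volumes_pL: dict[str, float] = {
        "P0": 24.8, "AB": 14.7, "P1": 10.1,
        "ABa": 7.35, "ABp": 7.35, "EMS": 6.1, "P2": 4.2,
    }
    k_syn_germline: float = Field(0.06, ge=0)     # nM/s
    k_deg_somatic: float = Field(0.003, ge=0)     # 1/s
    t_div1_s: float = 900.0
    t_div_ab_s: float = 1750.0
    t_div2_s: float = 1800.0
    maturation_delay_s: float = Field(0.0, ge=0)


class AnalysisConfig(_Strict):
    phi: float = Field(6.4, ge=1)                 # zygote -> P2 volume fold decrease
    observed_p2_nM: float = Field(424.0, gt=0)
    division_ratios: dict[str, float] = {"P0": 2.03, "P1": 1.91}
    alpha: float = Field(0.05, gt=0, lt=1)
    normalization: str = "prebleach"              # prebleach | control
    percent_decimals: int = 0
    ratio_decimals: int = 2


class RunConfig(_Strict):
    seed: int = 0
    outdir: Path | None = None
    optics: OpticsConfig = OpticsConfig()
    lineage: LineageConfig = LineageConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import json

        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.model_validate(yaml.safe_load(text))
        return cls.model_validate(json.loads(text))
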