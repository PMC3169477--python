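"""End-to-end phantom study runner.

Reproduces the design of a method-comparison volumetry study on digital
phantoms: for every heart, record the analytic ground truth, slice the
phantom with each short-axis protocol and the rotational long-axis
protocol, push the contours through each simulated observer, quantify
EDV/ESV/EF/mass with both methods, and summarize percent bias against
truth (the mold-comparison table analogue) and inter-observer
differences per method (the reproducibility table analogue).

The whole report is a pure function of the configuration: per-heart and
per-observer seeds derive from ``master_seed`` by a counter-based scheme
(seed sequences keyed on [master_seed, stage, heart, observer, protocol,
phase]), so adding hearts or observers never reshuffles existing ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import io as hio
from .geometry import LaxSet, SaxStack
from .lax import mass_lax, rotational_volume
from .observer import NoiseModel, perturb
from .phantom import (
    HeartPhantom,
    analytic_mass,
    analytic_volume,
    make_phantom,
    slice_lax,
    slice_sax,
)
from .sax import function_params, mass_sax, stack_volume

__all__ = ["ObserverConfig", "StudyConfig", "StudyResult", "run_study",
           "derive_seed"]

log = logging.getLogger(__name__)

_VOLUME_COLUMNS = ["heart", "method", "observer", "edv_ml", "esv_ml",
                   "sv_ml", "ef_pct", "mass_g", "la_ml"]


def derive_seed(master_seed: int, *path: int) -> int:
    """Stable counter-based sub-seed, always below 2**31."""
    return int(np.random.SeedSequence([master_seed, *path]).generate_state(1)[0]
               % (2 ** 31))


class ObserverConfig(BaseModel):
    """One simulated observer (seedless; seeds derive from the master)."""

    model_config = ConfigDict(extra="forbid")
    radial_sd: float = Field(0.5, ge=0)
    smoothness_scale: float = Field(30.0, gt=0)
    basal_shift: int = Field(0, ge=-1, le=1)
    basal_shift_prob: float = Field(0.0, ge=0.0, le=1.0)

    def noise(self, seed: int) -> NoiseModel:
        return NoiseModel(radial_sd=self.radial_sd,
                          smoothness_scale=self.smoothness_scale,
                          basal_shift=self.basal_shift,
                          basal_shift_prob=self.basal_shift_prob, seed=seed)


class StudyConfig(BaseModel):
    """Parameters of one simulated method-comparison study."""

    model_config = ConfigDict(extra="forbid")
    n_hearts: int = Field(12, ge=1)
    preset: Literal["canine", "human"] = "canine"
    sax_protocols: list[tuple[float, float]] = Field(
        default_factory=lambda: [(10.0, 0.0), (8.0, 0.0), (5.0, 0.0)])
    lax_planes: int = Field(6, ge=2)
    observers: list[ObserverConfig] = Field(default_factory=list)
    n_levels: int = Field(256, ge=8)
    n_vertices: int = Field(360, ge=16)
    density: float = Field(1.05, gt=0)
    clip: bool = True
    chord_correction: bool = True
    master_seed: int = 0
    output_dir: str | None = None

    def model_post_init(self, _ctx) -> None:
        for t, g in self.sax_protocols:
            if t <= 0 or g < 0:
                raise ValueError(f"invalid SAX protocol (thickness {t}, gap {g})")


@dataclass
class StudyResult:
    """Tables produced by :func:`run_study` (all pandas DataFrames)."""

    truth: pd.DataFrame
    volumes: pd.DataFrame
    bias: pd.DataFrame          # percent bias vs truth per method (Table-1 analogue)
    interobserver: pd.DataFrame  # |obs A - obs B| per method (Table-3 analogue)
    failures: list[str] = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"truth": self.truth, "volumes": self.volumes,
                "bias": self.bias, "interobserver": self.interobserver}


def _sax_label(thickness: float, gap: float) -> str:
    return f"SAX {thickness:g}mm" + (f" gap {gap:g}mm" if gap else "")


def _quantify_sax(ed: SaxStack, es: SaxStack, density: float,
                  clip: bool) -> dict[str, float]:
    edv = stack_volume(ed.select("LV", "endo", "ED"), clip=clip)
    esv = stack_volume(es.select("LV", "endo", "ES"), clip=clip)
    mass = mass_sax(es.select("LV", "endo", "ES"), es.select("LV", "epi", "ES"),
                    density=density, clip=clip)
    la = stack_volume(ed.select("LA", "endo", "ED"), clip=False)
    vs = function_params(edv, esv, mass, method="SAX")
    return {"edv_ml": vs.edv, "esv_ml": vs.esv, "sv_ml": vs.sv,
            "ef_pct": vs.ef, "mass_g": vs.mass, "la_ml": la}


def _quantify_lax(ed: LaxSet, es: LaxSet, density: float, n_levels: int,
                  chord_correction: bool) -> dict[str, float]:
    edv = rotational_volume(ed.select("LV", "endo", "ED"), n_levels,
                            chord_correction)
    esv = rotational_volume(es.select("LV", "endo", "ES"), n_levels,
                            chord_correction)
    mass = mass_lax(es, es, density=density, n_levels=n_levels,
                    chord_correction=chord_correction)
    la = rotational_volume(ed.select("LA", "endo", "ED"), n_levels,
                           chord_correction)
    vs = function_params(edv, esv, mass, method="LAX")
    return {"edv_ml": vs.edv, "esv_ml": vs.esv, "sv_ml": vs.sv,
            "ef_pct": vs.ef, "mass_g": vs.mass, "la_ml": la}


def _truth_row(heart: int, ph: HeartPhantom) -> dict[str, float]:
    edv = analytic_volume(ph, "LV", "endo", "ED")
    esv = analytic_volume(ph, "LV", "endo", "ES")
    return {"heart": heart, "edv_ml": edv, "esv_ml": esv, "sv_ml": edv - esv,
            "ef_pct": 100.0 * (edv - esv) / edv,
            "mass_g": analytic_mass(ph, "ES"),
            "la_ml": analytic_volume(ph, "LA", "endo", "ED")}


def _bias_table(volumes: pd.DataFrame, truth: pd.DataFrame,
                source_observer: str) -> pd.DataFrame:
    from .agreement import percent_bias_vs_truth

    rows = []
    sub = volumes[volumes["observer"] == source_observer]
    merged = sub.merge(truth, on="heart", suffixes=("", "_true"))
    for method, grp in merged.groupby("method", sort=True):
        row: dict[str, object] = {"method": method, "n": len(grp)}
        for col, label in (("edv_ml", "lv_volume"), ("la_ml", "la_volume"),
                           ("mass_g", "lv_mass")):
            _, mean, sd = percent_bias_vs_truth(grp[col].to_numpy(),
                                                grp[f"{col}_true"].to_numpy())
            row[f"{label}_bias_pct"] = mean
            row[f"{label}_bias_sd"] = sd
        rows.append(row)
    cols = ["method", "n", "lv_volume_bias_pct", "lv_volume_bias_sd",
            "la_volume_bias_pct", "la_volume_bias_sd",
            "lv_mass_bias_pct", "lv_mass_bias_sd"]
    return pd.DataFrame(rows, columns=cols)


def _interobserver_table(volumes: pd.DataFrame) -> pd.DataFrame:
    from .agreement import observer_differences

    obs = sorted(o for o in volumes["observer"].unique() if o.startswith("obs"))
    if len(obs) < 2:
        return pd.DataFrame(columns=["method", "n", "edv_absdiff_ml",
                                     "esv_absdiff_ml", "ef_absdiff_pct",
                                     "mass_absdiff_g"])
    a_name, b_name = obs[0], obs[1]
    rows = []
    for method, grp in volumes.groupby("method", sort=True):
        a = grp[grp["observer"] == a_name].sort_values("heart")
        b = grp[grp["observer"] == b_name].sort_values("heart")
        row = {"method": method, "n": len(a)}
        for col, label in (("edv_ml", "edv_absdiff_ml"),
                           ("esv_ml", "esv_absdiff_ml"),
                           ("ef_pct", "ef_absdiff_pct"),
                           ("mass_g", "mass_absdiff_g")):
            mean_abs, _ = observer_differences(a[col].to_numpy(), b[col].to_numpy())
            row[label] = mean_abs
        rows.append(row)
    return pd.DataFrame(rows, columns=["method", "n", "edv_absdiff_ml",
                                       "esv_absdiff_ml", "ef_absdiff_pct",
                                       "mass_absdiff_g"])


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full phantom study described by ``config``.

    A failing heart is logged and skipped; the run continues and the
    failures are summarized on the result. When ``config.output_dir`` is
    set, the tables are also written as deterministic CSV.
    """
    truth_rows: list[dict] = []
    volume_rows: list[dict] = []
    failures: list[str] = []

    for h in range(config.n_hearts):
        try:
            ph = make_phantom(config.preset, seed=derive_seed(config.master_seed, 1, h))
            truth_rows.append(_truth_row(h, ph))
            sliced: dict[str, tuple] = {}
            for p_idx, (t, g) in enumerate(config.sax_protocols):
                ed = slice_sax(ph, t, g, "ED", n_vertices=config.n_vertices)
                es = slice_sax(ph, t, g, "ES", n_vertices=config.n_vertices)
                sliced[_sax_label(t, g)] = ("sax", p_idx, ed, es)
            ed = slice_lax(ph, config.lax_planes, "ED", n_vertices=config.n_vertices)
            es = slice_lax(ph, config.lax_planes, "ES", n_vertices=config.n_vertices)
            sliced["LAX"] = ("lax", len(config.sax_protocols), ed, es)

            for method, (kind, p_idx, ed, es) in sliced.items():
                passes: list[tuple[str, SaxStack | LaxSet, SaxStack | LaxSet]] = \
                    [("ideal", ed, es)]
                for o_idx, ocfg in enumerate(config.observers):
                    n_ed = ocfg.noise(derive_seed(config.master_seed, 2, h, o_idx, p_idx, 0))
                    n_es = ocfg.noise(derive_seed(config.master_seed, 2, h, o_idx, p_idx, 1))
                    passes.append((f"obs{o_idx}", perturb(ed, n_ed), perturb(es, n_es)))
                for obs_name, ped, pes in passes:
                    if kind == "sax":
                        vals = _quantify_sax(ped, pes, config.density, config.clip)
                    else:
                        vals = _quantify_lax(ped, pes, config.density,
                                             config.n_levels, config.chord_correction)
                    volume_rows.append({"heart": h, "method": method,
                                        "observer": obs_name, **vals})
            log.info("heart %d quantified (%d methods)", h, len(sliced))
        except Exception as exc:  # noqa: BLE001 - per-heart isolation is the contract
            log.error("heart %d failed: %s", h, exc)
            failures.append(f"heart {h}: {exc}")

    truth = pd.DataFrame(truth_rows, columns=["heart", "edv_ml", "esv_ml",
                                              "sv_ml", "ef_pct", "mass_g", "la_ml"])
    volumes = pd.DataFrame(volume_rows, columns=_VOLUME_COLUMNS)
    source = "obs0" if config.observers else "ideal"
    if len(volumes):
        bias = _bias_table(volumes, truth, source)
        inter = _interobserver_table(volumes)
    else:
        bias = pd.DataFrame()
        inter = pd.DataFrame()
    result = StudyResult(truth, volumes, bias, inter, failures)
    if config.output_dir is not None:
        hio.write_results(result.tables(), Path(config.output_dir))
    if failures:
        log.warning("%d of %d hearts failed", len(failures), config.n_hearts)
    return result
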