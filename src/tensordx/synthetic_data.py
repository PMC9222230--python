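"""Synthetic multi-tissue two-strain time-course expression data.

Emulates the experimental design the pipeline targets: probes measured at
several time points, in several replicates, under two treatments, in two
strains (a disease model and a control), across several tissues.  A chosen
fraction of probes are planted as differentially expressed: they receive a
constant shift in one treatment arm — by default only in one strain, so the
signal lives in the treatment x strain interaction — uniformly across ALL
tissues.  That tissue-independent, treatment-distinct structure is exactly
the criterion the tensor pipeline selects for, so recovery against the
planted truth exercises every downstream stage.

Values are on a log-like scale: per-probe per-tissue Gaussian baselines
plus i.i.d. Gaussian noise, matching the Gaussian null assumed by the
chi-squared selection statistic.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geo_io import ExpressionTensor

TISSUE_NAMES = ("adipose", "muscle", "liver")


class SimulationConfigError(ValueError):
    """A configuration field is invalid; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    ``effect_size`` is the standardized mean shift added to DEG probes in
    the affected arm (treatment ``affected_treatment``, strain
    ``affected_strain``; set ``affected_strain=None`` to shift the whole
    treatment level in both strains).  ``time_ramp=True`` makes the shift
    grow linearly over time (mean over time points kept at ``effect_size``)
    instead of being constant.
    """

    n_probes: int
    n_times: int = 5
    n_replicates: int = 5
    n_treatments: int = 2
    n_strains: int = 2
    n_tissues: int = 3
    frac_deg: float = 0.1
    effect_size: float = 3.0
    noise_sd: float = 1.0
    tissue_baseline_sd: float = 1.0
    seed: int = 0
    affected_treatment: int = 1
    affected_strain: int | None = 1
    time_ramp: bool = False

    def validate(self) -> None:
        for name in ("n_probes", "n_times", "n_replicates", "n_treatments",
                     "n_strains", "n_tissues"):
            if int(getattr(self, name)) < 1:
                raise SimulationConfigError(f"{name} must be >= 1")
        if not 0.0 <= self.frac_deg < 1.0:
            raise SimulationConfigError("frac_deg must be in [0, 1)")
        if self.frac_deg > 0 and round(self.frac_deg * self.n_probes) < 1:
            raise SimulationConfigError(
                "frac_deg: frac_deg * n_probes must be >= 1 when frac_deg > 0")
        if self.noise_sd <= 0:
            raise SimulationConfigError("noise_sd must be > 0")
        if self.tissue_baseline_sd < 0:
            raise SimulationConfigError("tissue_baseline_sd must be >= 0")
        if not 0 <= self.affected_treatment < self.n_treatments:
            raise SimulationConfigError(
                "affected_treatment must index a treatment level")
        if self.affected_strain is not None and not (
                0 <= self.affected_strain < self.n_strains):
            raise SimulationConfigError("affected_strain must index a strain level")

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.n_probes, self.n_times, self.n_replicates,
                self.n_treatments, self.n_strains, self.n_tissues)


@dataclass
class SyntheticTruth:
    """Planted ground truth: which probes are DEGs and their shifts."""

    deg_flags: np.ndarray            # bool, per probe
    effects: np.ndarray              # signed shift per probe (0 for non-DEG)
    affected_treatment: int
    affected_strain: int | None

    @property
    def n_deg(self) -> int:
        return int(self.deg_flags.sum())

    def deg_probe_ids(self, probe_ids: list[str]) -> set[str]:
        return {p for p, f in zip(probe_ids, self.deg_flags) if f}


def _tissue_labels(n_tissues: int) -> list[str]:
    if n_tissues <= len(TISSUE_NAMES):
        return list(TISSUE_NAMES[:n_tissues])
    return list(TISSUE_NAMES) + [f"tissue{t}" for t in range(len(TISSUE_NAMES), n_tissues)]


def generate_dataset(config: SimulationConfig) -> tuple[ExpressionTensor, SyntheticTruth]:
    """Draw one synthetic experiment; bit-reproducible for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_probes

    n_deg = int(round(config.frac_deg * n))
    deg_idx = rng.choice(n, size=n_deg, replace=False)
    deg_flags = np.zeros(n, dtype=bool)
    deg_flags[deg_idx] = True
    effects = np.where(deg_flags, float(config.effect_size), 0.0)

    # per-probe per-tissue baseline, constant over samples within a tissue
    baseline = rng.normal(0.0, config.tissue_baseline_sd,
                          size=(n, config.n_tissues))
    values = baseline[:, None, None, None, None, :] * np.ones(config.shape)

    if config.time_ramp and config.n_times > 1:
        ramp = np.linspace(0.0, 2.0, config.n_times)   # mean 1 over time
    else:
        ramp = np.ones(config.n_times)
    shift = effects[:, None] * ramp[None, :]           # (probe, time)
    strain_sel = (slice(None) if config.affected_strain is None
                  else config.affected_strain)
    values[:, :, :, config.affected_treatment, strain_sel, :] += (
        shift[:, :, None, None] if config.affected_strain is not None
        else shift[:, :, None, None, None])

    values += rng.normal(0.0, config.noise_sd, size=config.shape)

    probe_ids = [f"probe_{i:06d}" for i in range(n)]
    axis_labels = {
        "time": [str(j) for j in range(config.n_times)],
        "replicate": [str(k) for k in range(config.n_replicates)],
        "treatment": [str(m) for m in range(config.n_treatments)],
        "strain": [str(s) for s in range(config.n_strains)],
        "tissue": _tissue_labels(config.n_tissues),
    }
    tensor = ExpressionTensor(values, probe_ids, axis_labels)
    truth = SyntheticTruth(deg_flags=deg_flags, effects=effects,
                           affected_treatment=config.affected_treatment,
                           affected_strain=config.affected_strain)
    return tensor, truth


def write_series_matrices(tensor: ExpressionTensor, out_dir: str | Path,
                          fmt: str = "%.6g", compress: bool = False) -> list[Path]:
    """Write one series-matrix-style file per tissue.

    Sample metadata encodes the design in the canonical form the default
    parsing rules understand (``time: j``, ``replicate: k`` ... lines).
    ``fmt`` controls numeric precision (default 6 significant digits;
    pass ``"%.17g"`` for an exact round-trip).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    x = tensor.values
    _, n_time, n_rep, n_trt, n_str, n_tis = x.shape
    tissues = tensor.axis_labels.get(
        "tissue", [f"tissue{t}" for t in range(n_tis)])
    paths = []
    for t, tissue in enumerate(tissues):
        cells = [(j, k, m, s)
                 for j in range(n_time) for k in range(n_rep)
                 for m in range(n_trt) for s in range(n_str)]
        sample_ids = [f"{tissue}_j{j}k{k}m{m}s{s}" for j, k, m, s in cells]
        lines = [f"!Series_title\t\"synthetic {tissue} expression\""]
        lines.append("\t".join(["!Sample_geo_accession"] + sample_ids))
        lines.append("\t".join(
            ["!Sample_characteristics_ch1"] + [f"tissue: {tissue}"] * len(cells)))
        for fieldname, pos in (("time", 0), ("replicate", 1),
                               ("treatment", 2), ("strain", 3)):
            lines.append("\t".join(
                ["!Sample_characteristics_ch1"]
                + [f"{fieldname}: {cell[pos]}" for cell in cells]))
        lines.append("!series_matrix_table_begin")
        lines.append("\t".join(["ID_REF"] + sample_ids))
        for i, probe in enumerate(tensor.probe_ids):
            row = [fmt % x[i, j, k, m, s, t] for j, k, m, s in cells]
            lines.append("\t".join([probe] + row))
        lines.append("!series_matrix_table_end")
        text = "\n".join(lines) + "\n"
        name = f"{tissue}_series_matrix.txt" + (".gz" if compress else "")
        path = out_dir / name
        if compress:
            with gzip.open(path, "wt", encoding="utf-8") as fh:
                fh.write(text)
        else:
            path.write_text(text, encoding="utf-8")
        paths.append(path)
    return paths


def write_truth(truth: SyntheticTruth, probe_ids: list[str],
                path: str | Path) -> Path:
    """Write planted labels as a 2-column TSV (probe_id, is_deg)."""
    path = Path(path)
    pd.DataFrame({"probe_id": probe_ids,
                  "is_deg": truth.deg_flags.astype(int)}).to_csv(
        path, sep="\t", index=False)
    return path
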