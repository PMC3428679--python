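"""Readers, writers, run configuration and the end-to-end pipeline.

Input dialect
-------------
* matrix: tab-delimited, first column the sample id, remaining column
  headers the probe ids; one row per sample.
* probe annotation: tab-delimited with header ``probe_id  chrom  position``.
* alternative "long" segment table: ``sample  chrom  start  end  log2ratio``
  (positions in bp, closed intervals), expanded onto the probe grid by the
  loader; probes not covered by any segment are neutral (0.0).

Output coordinates: the calls TSV reports 1-based closed probe indices and
bp positions of the first/last probe; BED intervals are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_units import (
    AMPLIFICATION,
    TAILS,
    ConfigurationError,
    CopyNumberMatrix,
    DataQualityError,
    chromosome_sort_key,
)
from .iterative import IterativeResult, SAICParams, run_algorithm2, significance_threshold
from .significance import CHROMOSOME, SCACall

logger = logging.getLogger("saic")

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY", "x", "y"}


@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a detection run."""

    matrix: str = ""
    probes: str = ""
    segments: str = ""          #: long-format alternative to ``matrix``
    output_dir: str = "saic_out"
    theta_amp: float = 0.263
    theta_del: float = -0.322
    theta_rho: float = 0.95
    permutations: int = 1000
    alpha: float = 0.05
    scope: str = CHROMOSOME
    seed: int = 0
    max_iterations: int = 50
    split_sex: bool = True      #: analyse X/Y separately from autosomes
    log_level: str = "INFO"

    def params(self) -> SAICParams:
        return SAICParams(theta_amp=self.theta_amp, theta_del=self.theta_del,
                          theta_rho=self.theta_rho,
                          permutations=self.permutations, alpha=self.alpha,
                          scope=self.scope, seed=self.seed,
                          max_iterations=self.max_iterations)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def _load_annotation(annotation_path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"probe_id": str,
                                                        "chrom": str})
    required = {"probe_id", "chrom", "position"}
    if not required.issubset(ann.columns):
        raise DataQualityError(
            f"{annotation_path}: annotation needs columns {sorted(required)}")
    if ann["probe_id"].duplicated().any():
        dup = ann.loc[ann["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise DataQualityError(f"{annotation_path}: duplicate probe {dup!r}")
    return ann


def _sorted_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    key = ann["chrom"].map(chromosome_sort_key)
    order = sorted(range(len(ann)), key=lambda i: (key.iloc[i],
                                                   ann["position"].iloc[i]))
    return ann.iloc[order].reset_index(drop=True)


def load_matrix(matrix_path: str | Path,
                annotation_path: str | Path) -> CopyNumberMatrix:
    """Load a wide-format log2-ratio matrix with its probe annotation.

    Probes are re-ordered into canonical (chromosome, position) order;
    duplicate probes, shape mismatches, missing and non-numeric values are
    rejected with named errors.
    """
    ann = _sorted_annotation(_load_annotation(annotation_path))
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if df.shape[1] != len(ann):
        raise DataQualityError(
            f"{matrix_path}: matrix has {df.shape[1]} probe columns but "
            f"annotation lists {len(ann)} probes")
    missing = set(map(str, df.columns)) ^ set(ann["probe_id"])
    if missing:
        raise DataQualityError(
            f"{matrix_path}: probe ids do not match annotation "
            f"(e.g. {sorted(missing)[:3]})")
    df = df[ann["probe_id"]]
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad_col = next(c for c in df.columns
                       if not np.issubdtype(df[c].dtype, np.number))
        raise DataQualityError(
            f"{matrix_path}: non-numeric values in probe column {bad_col!r}")
    if np.isnan(values).any():
        n, m = np.argwhere(np.isnan(values))[0]
        raise DataQualityError(
            f"{matrix_path}: missing value for sample {df.index[n]!r} at "
            f"probe {df.columns[m]!r} (segmented input must be complete)")
    return CopyNumberMatrix(
        values=values.astype(np.float64),
        samples=[str(s) for s in df.index],
        probe_ids=ann["probe_id"].to_numpy(dtype=object),
        chromosomes=ann["chrom"].to_numpy(dtype=object),
        positions=ann["position"].to_numpy(dtype=np.int64),
    )


def load_segments(segments_path: str | Path,
                  annotation_path: str | Path) -> CopyNumberMatrix:
    """Expand a long-format segment table onto the probe grid.

    Each probe takes the log2 ratio of the segment covering its position
    (same chromosome, start <= position <= end); uncovered probes are 0.
    """
    ann = _sorted_annotation(_load_annotation(annotation_path))
    seg = pd.read_csv(segments_path, sep="\t",
                      dtype={"sample": str, "chrom": str})
    required = {"sample", "chrom", "start", "end", "log2ratio"}
    if not required.issubset(seg.columns):
        raise DataQualityError(
            f"{segments_path}: segment table needs columns {sorted(required)}")
    samples = list(dict.fromkeys(seg["sample"]))
    if len(samples) < 2:
        raise DataQualityError(f"{segments_path}: need at least 2 samples")
    values = np.zeros((len(samples), len(ann)))
    sample_idx = {s: i for i, s in enumerate(samples)}
    chrom = ann["chrom"].to_numpy()
    pos = ann["position"].to_numpy()
    for row in seg.itertuples(index=False):
        mask = (chrom == row.chrom) & (pos >= row.start) & (pos <= row.end)
        values[sample_idx[row.sample], mask] = row.log2ratio
    return CopyNumberMatrix(
        values=values,
        samples=samples,
        probe_ids=ann["probe_id"].to_numpy(dtype=object),
        chromosomes=ann["chrom"].to_numpy(dtype=object),
        positions=ann["position"].to_numpy(dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _call_rows(calls: list[SCACall], X: CopyNumberMatrix) -> list[dict]:
    rows = []
    for c in sorted(calls, key=lambda c: (chromosome_sort_key(c.unit.chromosome),
                                          c.unit.k, c.tail)):
        u = c.unit
        rows.append(dict(
            chrom=u.chromosome,
            start_bp=int(X.positions[u.k]),
            end_bp=int(X.positions[u.stop - 1]),
            start_probe=u.k + 1,
            end_probe=u.stop,
            L=u.L,
            tail=c.tail,
            U=c.score,
            P=c.pvalue,
            iteration=c.iteration,
        ))
    return rows


def write_calls_tsv(calls: list[SCACall], X: CopyNumberMatrix,
                    path: str | Path) -> None:
    """SCA table: 1-based closed probe indices, bp span, U, P, iteration."""
    cols = ["chrom", "start_bp", "end_bp", "start_probe", "end_probe", "L",
            "tail", "U", "P", "iteration"]
    pd.DataFrame(_call_rows(calls, X), columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def write_calls_bed(calls: list[SCACall], X: CopyNumberMatrix,
                    path: str | Path) -> None:
    """BED5 (0-based half-open): name = tail, score = -1000 log10 P capped."""
    lines = []
    for r in _call_rows(calls, X):
        score = min(1000, int(round(-1000 * np.log10(r["P"]))))
        lines.append(f"{r['chrom']}\t{r['start_bp'] - 1}\t{r['end_bp']}\t"
                     f"{r['tail']}\t{score}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_landscape(result: IterativeResult, X: CopyNumberMatrix,
                    path: str | Path) -> None:
    """Per-unit -log10 P table over the whole genome, for landscape plots."""
    rows = []
    for tail in TAILS:
        for c in result.candidates[tail]:
            u = c.unit
            rows.append(dict(
                chrom=u.chromosome,
                start_bp=int(X.positions[u.k]),
                end_bp=int(X.positions[u.stop - 1]),
                L=u.L, tail=tail, U=c.score, P=c.pvalue,
                neglog10P=-np.log10(c.pvalue),
            ))
    cols = ["chrom", "start_bp", "end_bp", "L", "tail", "U", "P", "neglog10P"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False,
                                            float_format="%.6g")


def write_manifest(cfg: RunConfig, result: IterativeResult,
                   path: str | Path) -> None:
    manifest = dict(
        config=dataclasses.asdict(cfg),
        alpha_prime=significance_threshold(cfg.alpha),
        iterations_run=result.iterations_run,
        n_calls=len(result.calls),
        versions=dict(saic=__version__, numpy=np.__version__),
    )
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def plot_landscape(result: IterativeResult, X: CopyNumberMatrix,
                   path: str | Path, alpha: float = 0.05) -> None:
    """Minimal -log10 P landscape figure (amplification up, deletion down)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for tail, sign, color in ((AMPLIFICATION, 1, "tab:red"),
                              ("deletion", -1, "tab:blue")):
        for c in result.candidates[tail]:
            y = sign * -np.log10(c.pvalue)
            ax.plot([c.unit.k, c.unit.stop - 1], [y, y], color=color, lw=1.5)
    thr = -np.log10(significance_threshold(alpha))
    ax.axhline(thr, ls="--", c="gray", lw=0.8)
    ax.axhline(-thr, ls="--", c="gray", lw=0.8)
    ax.axhline(0, c="black", lw=0.5)
    ax.set_xlabel("probe index")
    ax.set_ylabel("signed -log10 P")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _merge_results(parts: list[IterativeResult], alpha: float) -> IterativeResult:
    merged = IterativeResult(
        calls=[c for p in parts for c in p.calls],
        iterations_run=max(p.iterations_run for p in parts),
        alpha=alpha,
        alpha_prime=significance_threshold(alpha),
        final_null={}, candidates={t: [] for t in TAILS},
        units={t: [] for t in TAILS},
        iteration_pvalues={t: [] for t in TAILS},
    )
    for p in parts:
        for t in TAILS:
            merged.candidates[t].extend(p.candidates[t])
            merged.units[t].extend(p.units[t])
    return merged


def run_pipeline(cfg: RunConfig) -> IterativeResult:
    """Load -> decompose -> iterate -> write TSV/BED/landscape/manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    if cfg.segments:
        X = load_segments(cfg.segments, cfg.probes)
    elif cfg.matrix:
        X = load_matrix(cfg.matrix, cfg.probes)
    else:
        raise ConfigurationError("config needs either 'matrix' or 'segments'")
    groups: list[tuple[CopyNumberMatrix, int]] = []
    sex = [c for c in dict.fromkeys(map(str, X.chromosomes)) if c in SEX_CHROMOSOMES]
    auto = [c for c in dict.fromkeys(map(str, X.chromosomes)) if c not in SEX_CHROMOSOMES]
    if cfg.split_sex and sex and auto:
        groups.append((X.select_chromosomes(auto), 0))
        groups.append((X.select_chromosomes(sex), 1))
    else:
        groups.append((X, 0))
    parts = []
    for sub, gi in groups:
        params = cfg.params()
        if gi:
            params = dataclasses.replace(
                params, seed=int(np.random.SeedSequence((cfg.seed, 9000 + gi))
                                 .generate_state(1)[0] & 0x7FFFFFFF))
        parts.append((sub, run_algorithm2(sub, params)))
    result = _merge_results([r for _, r in parts], cfg.alpha)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    # per-group coordinates differ, so write per group and concatenate
    frames = []
    bed_lines = []
    land_frames = []
    for sub, r in parts:
        frames.extend(_call_rows(r.calls, sub))
        tmp_bed = outdir / "_part.bed"
        write_calls_bed(r.calls, sub, tmp_bed)
        bed_lines.append(tmp_bed.read_text())
        tmp_land = outdir / "_part_land.tsv"
        write_landscape(r, sub, tmp_land)
        land_frames.append(pd.read_csv(tmp_land, sep="\t"))
        tmp_bed.unlink()
        tmp_land.unlink()
    cols = ["chrom", "start_bp", "end_bp", "start_probe", "end_probe", "L",
            "tail", "U", "P", "iteration"]
    pd.DataFrame(frames, columns=cols).to_csv(outdir / "sca_calls.tsv",
                                              sep="\t", index=False,
                                              float_format="%.6g")
    (outdir / "sca_calls.bed").write_text("".join(bed_lines))
    pd.concat(land_frames, ignore_index=True).to_csv(
        outdir / "landscape.tsv", sep="\t", index=False, float_format="%.6g")
    write_manifest(cfg, result, outdir / "manifest.json")
    logger.info("wrote %d call(s) to %s", len(result.calls), outdir)
    return result
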