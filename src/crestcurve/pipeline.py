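"""End-to-end orchestration: simulate/read -> resample -> align -> stats -> fields.

``run_study`` executes the whole analysis from a single :class:`RunConfig`
and writes a report bundle: the semilandmark table, the aligned sample (HDF5
container), a PCA summary, the pairwise shape-test and length-test p-value
matrices, an allometry table, difference-field exports for the extreme and
adjacent chronological comparisons, PC1-PC2 ellipse specs per group, and a
run manifest (config hash, seed, version, warnings) sufficient to reproduce
the bundle.

Each stage consumes only the previous stage's output; the master seed fans
out to per-stage and per-cell child seeds through a label-keyed derivation,
so adding or removing one group does not perturb the other cells.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .curve_io import (
    SemilandmarkTable,
    read_asc_polyline,
    read_semilandmark_table,
    table_from_curves,
    write_semilandmark_table,
)
from .errors import InvalidParameterError
from .mean_shapes import (
    anatomical_frame,
    confidence_ellipse,
    difference_field,
    group_mean,
)
from .resampling import DEFAULT_K, resample_equidistant
from .shape_stats import (
    DEFAULT_ALPHA,
    DEFAULT_PERMUTATIONS,
    PairwiseTestMatrix,
    PCAModel,
    allometry_anova,
    pairwise_group_tests,
    pairwise_scalar_tests,
    pca_shapes,
)
from .superimposition import AlignedSample, gpa, slide_semilandmarks
from .synthetic import StudyDesign, generate_study

logger = logging.getLogger(__name__)


def _pkg_version() -> str:
    from . import __version__
    return __version__


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    design: StudyDesign | None = None  # synthetic input ...
    input_dir: str | Path | None = None  # ... or a directory of .asc files
    metadata_csv: str | Path | None = None  # required with input_dir
    out_dir: str | Path = "crestcurve_run"
    k: int = DEFAULT_K
    slide: bool = True
    slide_tol: float = 1e-8
    max_passes: int = 10
    n_permutations: int = DEFAULT_PERMUTATIONS
    alpha: float = DEFAULT_ALPHA
    seed: int | None = None
    by_sex: bool = True

    def validate(self) -> None:
        if (self.design is None) == (self.input_dir is None):
            raise InvalidParameterError(
                "exactly one of design / input_dir must be provided"
            )
        if self.input_dir is not None:
            if self.metadata_csv is None:
                raise InvalidParameterError("input_dir requires metadata_csv")
            for p in (self.input_dir, self.metadata_csv):
                if not Path(p).exists():
                    raise InvalidParameterError(f"path does not exist: {p}")

    def to_dict(self) -> dict:
        d = {
            "input_dir": str(self.input_dir) if self.input_dir else None,
            "metadata_csv": str(self.metadata_csv) if self.metadata_csv else None,
            "out_dir": str(self.out_dir),
            "k": self.k,
            "slide": self.slide,
            "slide_tol": self.slide_tol,
            "max_passes": self.max_passes,
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "seed": self.seed,
            "by_sex": self.by_sex,
            "design": self.design.to_dict() if self.design else None,
        }
        return d


@dataclass
class ReportBundle:
    table: SemilandmarkTable
    aligned: AlignedSample
    pca: PCAModel
    shape_tests: PairwiseTestMatrix
    length_tests: PairwiseTestMatrix
    allometry: pd.DataFrame
    fields: dict[str, pd.DataFrame]
    ellipses: dict[str, dict]
    manifest: dict
    out_dir: Path = field(default=Path("."))


def write_aligned_h5(aligned: AlignedSample, path: str | Path) -> None:
    """Store an aligned sample in a single HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("shapes", data=aligned.shapes)
        f.create_dataset("consensus", data=aligned.consensus)
        f.create_dataset("centroid_sizes", data=aligned.centroid_sizes)
        f.create_dataset("curve_lengths", data=aligned.curve_lengths)
        ids = np.array(aligned.specimen_ids, dtype=h5py.string_dtype())
        f.create_dataset("specimen_ids", data=ids)
        f.attrs["iterations"] = json.dumps(aligned.iterations)
        f.attrs["n_skipped_slides"] = aligned.n_skipped_slides


def read_aligned_h5(path: str | Path) -> AlignedSample:
    with h5py.File(path, "r") as f:
        return AlignedSample(
            shapes=f["shapes"][()],
            consensus=f["consensus"][()],
            centroid_sizes=f["centroid_sizes"][()],
            curve_lengths=f["curve_lengths"][()],
            specimen_ids=[s.decode() for s in f["specimen_ids"][()]],
            iterations=json.loads(f.attrs["iterations"]),
            n_skipped_slides=int(f.attrs["n_skipped_slides"]),
        )


def _load_table(config: RunConfig) -> SemilandmarkTable:
    """Stage 1+2: obtain polylines (synthetic or from disk) and resample."""
    if config.design is not None:
        design = config.design
        if design.seed is None and config.seed is not None:
            design = StudyDesign.from_dict({**design.to_dict(), "seed": config.seed})
        specimens = generate_study(design)
        curves = [
            resample_equidistant(sp.polyline, k=config.k, specimen_id=sp.specimen_id)
            for sp in specimens
        ]
        groups = [sp.meta["group"] for sp in specimens]
        sexes = [sp.meta["sex"] for sp in specimens]
        return table_from_curves(curves, groups, sexes)
    meta = pd.read_csv(config.metadata_csv, dtype=str)
    curves, groups, sexes = [], [], []
    for row in meta.itertuples():
        poly = read_asc_polyline(Path(config.input_dir) / f"{row.specimen_id}.asc")
        curves.append(resample_equidistant(poly, k=config.k, specimen_id=row.specimen_id))
        groups.append(row.group)
        sexes.append(getattr(row, "sex", "U"))
    return table_from_curves(curves, groups, sexes)


def _field_frame(df) -> pd.DataFrame:
    return pd.DataFrame({
        "semilandmark": np.arange(1, len(df.vectors) + 1),
        "dx": df.vectors[:, 0], "dy": df.vectors[:, 1], "dz": df.vectors[:, 2],
        "magnitude": df.magnitudes,
        "ap_u": df.ap_projection[:, 0], "ap_v": df.ap_projection[:, 1],
        "ml_u": df.ml_projection[:, 0], "ml_v": df.ml_projection[:, 1],
    })


def run_study(config: RunConfig) -> ReportBundle:
    """Execute the full pipeline and write the report bundle to disk."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    table = _load_table(config)
    write_semilandmark_table(table, out / "semilandmarks.csv")
    logger.info("stage resample: %d specimens, k=%d", table.n, table.k)

    curves = table.coords
    aligned = gpa(curves, canonicalize=not config.slide)
    if config.slide:
        aligned = slide_semilandmarks(
            aligned, tol=config.slide_tol, max_passes=config.max_passes
        )
    aligned.curve_lengths = table.curve_lengths_mm.copy()
    aligned.specimen_ids = list(table.specimen_ids)
    write_aligned_h5(aligned, out / "aligned.h5")
    if aligned.n_skipped_slides:
        warnings.append(f"{aligned.n_skipped_slides} semilandmark slides skipped")

    pca = pca_shapes(aligned)
    pd.DataFrame({
        "component": np.arange(1, len(pca.eigenvalues) + 1),
        "eigenvalue": pca.eigenvalues,
        "variance_fraction": pca.variance_fractions,
        "retained_broken_stick": np.arange(1, len(pca.eigenvalues) + 1)
        <= pca.n_retained_broken_stick,
    }).to_csv(out / "pca_summary.csv", index=False)

    group_order = table.group_levels
    shape_tests = pairwise_group_tests(
        pca, table.groups, n_permutations=config.n_permutations,
        alpha=config.alpha, seed=config.seed, group_order=group_order,
    )
    shape_tests.to_dataframe().to_csv(out / "shape_test_matrix.csv")

    length_tests = pairwise_scalar_tests(
        table.curve_lengths_mm, table.groups,
        n_permutations=config.n_permutations, alpha=config.alpha,
        seed=config.seed, group_order=group_order,
    )
    length_tests.to_dataframe().to_csv(out / "length_test_matrix.csv")

    strata = list(table.sexes) if config.by_sex else None
    allo_rows = allometry_anova(pca, table.curve_lengths_mm, strata=None)
    if config.by_sex:
        allo_rows += allometry_anova(pca, table.curve_lengths_mm, strata=strata)
    allometry = pd.DataFrame([vars(a) for a in allo_rows])
    allometry.to_csv(out / "allometry.csv", index=False)

    # difference fields in the shared frame of the pooled consensus
    frame = anatomical_frame(aligned.consensus)
    groups_arr = np.asarray(table.groups)
    means = {lab: group_mean(aligned, np.flatnonzero(groups_arr == lab))
             for lab in group_order}
    comparisons = [(group_order[0], group_order[-1])] + [
        (a, b) for a, b in zip(group_order[:-1], group_order[1:])
    ]
    fields: dict[str, pd.DataFrame] = {}
    for ref, tgt in dict.fromkeys(comparisons):
        df = difference_field(means[ref], means[tgt], frame, ref, tgt)
        fdf = _field_frame(df)
        fields[f"{ref}_vs_{tgt}"] = fdf
        fdf.to_csv(out / f"field_{ref}_vs_{tgt}.csv", index=False)

    ellipses: dict[str, dict] = {}
    if pca.scores.shape[1] >= 2:
        for lab in group_order:
            sel = groups_arr == lab
            if sel.sum() >= 3:
                e = confidence_ellipse(pca.scores[sel, :2])
                ellipses[lab] = {
                    "center": e.center.tolist(),
                    "semi_axes": e.semi_axes.tolist(),
                    "orientation": e.orientation,
                    "level": e.level,
                }
    with open(out / "ellipses.json", "w") as fh:
        json.dump(ellipses, fh, indent=2)

    cfg = config.to_dict()
    manifest = {
        "version": _pkg_version(),
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "n_specimens": table.n,
        "k": table.k,
        "groups": {lab: int(np.count_nonzero(groups_arr == lab)) for lab in group_order},
        "n_retained_pcs": int(max(1, pca.n_retained_broken_stick)),
        "warnings": warnings,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return ReportBundle(
        table=table, aligned=aligned, pca=pca, shape_tests=shape_tests,
        length_tests=length_tests, allometry=allometry, fields=fields,
        ellipses=ellipses, manifest=manifest, out_dir=out,
    )


def pairwise_report(bundle: ReportBundle, alpha: float | None = None) -> dict[str, pd.DataFrame]:
    """Formatted lower-triangular p-value matrices with significance flags."""
    mats = {}
    for name, tests in (("shape", bundle.shape_tests), ("length", bundle.length_tests)):
        if alpha is not None:
            tests = PairwiseTestMatrix(tests.labels, tests.p_values, tests.results, alpha)
        mats[name] = tests.to_dataframe()
    return mats
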