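"""End-to-end orchestration: normalise -> order -> segment -> correct -> counts.

:func:`correct_screen` is the in-memory pipeline used by the CLI, the tests
and any programmatic caller; :func:`run_pipeline` wraps it with file I/O and
a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .correction import CorrectionParams, CorrectionResult, clean_profile
from .counts import CorrectedCounts, invert_to_counts
from .io import (
    CountTable,
    read_counts,
    read_library,
    sort_by_genome,
    write_counts,
    write_segments,
)
from .normalisation import (
    DEFAULT_MIN_PLASMID_READS,
    DEFAULT_PSEUDOCOUNT,
    NormalisationResult,
    compute_logfc,
    normalise_screen,
)
from .segmentation import CbsParams

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ScreenResult:
    """Everything the pipeline produced for one screen."""

    normalisation: NormalisationResult
    profile: pd.DataFrame  # genome-ordered, uncorrected
    correction: CorrectionResult
    corrected_counts: CorrectedCounts
    dropped_guides: list[str]


def correct_screen(
    library: pd.DataFrame,
    counts: CountTable,
    min_reads: int = DEFAULT_MIN_PLASMID_READS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    cbs_params: CbsParams | None = None,
    correction_params: CorrectionParams | None = None,
) -> ScreenResult:
    """Run the full correction pipeline in memory."""
    norm = normalise_screen(counts, min_reads)
    log.info(
        "normalise: %d guides in, %d filtered (<%d plasmid reads)",
        len(counts.data),
        len(norm.filtered_guides),
        min_reads,
    )
    unordered = compute_logfc(norm, pseudocount)
    profile, dropped = sort_by_genome(unordered, library)
    log.info("order: %d guides placed, %d dropped (not in library)", len(profile), len(dropped))
    correction = clean_profile(profile, cbs_params, correction_params)
    n_corrected = sum(s.corrected for s in correction.segments)
    log.info(
        "segment/correct: %d segments, %d corrected",
        len(correction.segments),
        n_corrected,
    )
    corrected_logfc = correction.corrected_profile.set_index("sgRNA")["logFC"]
    # restrict counts to guides that survived filtering and ordering
    keep = norm.table.guides.isin(corrected_logfc.index)
    aligned = norm.table.replace_data(norm.table.data.loc[keep])
    corrected_counts = invert_to_counts(corrected_logfc, aligned)
    return ScreenResult(
        normalisation=norm,
        profile=profile,
        correction=correction,
        corrected_counts=corrected_counts,
        dropped_guides=dropped,
    )


# ---------------------------------------------------------------------------
# file-level run with manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(
    library_path: str | Path,
    counts_path: str | Path,
    output_dir: str | Path,
    min_reads: int = DEFAULT_MIN_PLASMID_READS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    cbs_params: CbsParams | None = None,
    correction_params: CorrectionParams | None = None,
) -> Path:
    """File-in, file-out pipeline; writes all artefacts plus a run manifest."""
    cbs_params = cbs_params or CbsParams()
    correction_params = correction_params or CorrectionParams()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "normalize"
    try:
        library = read_library(library_path)
        counts = read_counts(counts_path)
        norm = normalise_screen(counts, min_reads)
        unordered = compute_logfc(norm, pseudocount)
        stage = "segment"
        profile, dropped = sort_by_genome(unordered, library)
        result = clean_profile(profile, cbs_params, correction_params)
        stage = "counts"
        corrected_logfc = result.corrected_profile.set_index("sgRNA")["logFC"]
        keep = norm.table.guides.isin(corrected_logfc.index)
        aligned = norm.table.replace_data(norm.table.data.loc[keep])
        corrected_counts = invert_to_counts(corrected_logfc, aligned)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    write_counts(norm.table, out / "normalised_counts.tsv")
    norm.size_factors.to_frame().to_csv(out / "size_factors.tsv", sep="\t")
    profile.to_csv(out / "logfc.tsv", sep="\t", index=False)
    result.corrected_profile.to_csv(out / "corrected_logfc.tsv", sep="\t", index=False)
    result.offsets.rename_axis("sgRNA").to_frame().to_csv(
        out / "offsets.tsv", sep="\t"
    )
    write_segments(result.segments, profile, out / "segments.tsv")
    write_counts(corrected_counts.table, out / "corrected_counts.tsv")

    manifest = {
        "tool": "screenclean",
        "version": __version__,
        "parameters": {
            "min_reads": min_reads,
            "pseudocount": pseudocount,
            "alpha": cbs_params.alpha,
            "nperm": cbs_params.nperm,
            "min_width": cbs_params.min_width,
            "seed": cbs_params.seed,
            "min_genes": correction_params.min_genes,
            "center": correction_params.center,
            "exclude_genes": sorted(correction_params.exclude_genes),
        },
        "inputs": {
            "library": {"path": str(library_path), "sha256": _sha256(Path(library_path))},
            "counts": {"path": str(counts_path), "sha256": _sha256(Path(counts_path))},
        },
        "guides": {
            "input": len(counts.data),
            "filtered_low_plasmid": len(norm.filtered_guides),
            "dropped_no_coordinates": len(dropped),
            "analysed": len(profile),
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
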