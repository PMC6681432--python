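"""Dataset filtering for crystal-structure collections.

Replicates the corpus-selection rules used for crystal-water TWN
surveys: drop non-protein entries (nucleic-acid-only files), drop
structures without crystal waters, and keep only X-ray structures
refined at resolution better than the cutoff (default strictly below
1.6 Angstrom, the regime with a continuous surface hydration layer).
Rules apply in that order; a file is charged to the first rule it
fails.  Unknown resolution fails the resolution rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import FormatError
from .io import StructureMeta, read_structure

logger = logging.getLogger(__name__)

REASONS = ("non-protein", "no-water", "resolution")


@dataclass
class FilterConfig:
    """Corpus filtering rules."""

    resolution_cutoff_A: float = 1.6
    require_waters: bool = True
    exclude_nonprotein: bool = True

    def __post_init__(self) -> None:
        if self.resolution_cutoff_A <= 0:
            raise ValueError("resolution_cutoff_A must be positive")


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: str | None = None  # one of REASONS when keep is False


@dataclass
class FilterReport:
    """Per-rule drop counts; reconciles to the number of inputs."""

    n_input: int = 0
    n_dropped_nonprotein: int = 0
    n_dropped_nowater: int = 0
    n_dropped_resolution: int = 0
    n_unparseable: int = 0
    n_kept: int = 0
    decisions: list[tuple[str, str]] = field(default_factory=list)

    def reconciles(self) -> bool:
        return self.n_input == (
            self.n_kept
            + self.n_dropped_nonprotein
            + self.n_dropped_nowater
            + self.n_dropped_resolution
            + self.n_unparseable
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            for k in (
                "n_input",
                "n_dropped_nonprotein",
                "n_dropped_nowater",
                "n_dropped_resolution",
                "n_unparseable",
                "n_kept",
            ):
                fh.write(f"{k}\t{getattr(self, k)}\n")


def filter_structure(meta: StructureMeta, config: FilterConfig | None = None) -> FilterDecision:
    """Apply the rules in order: non-protein, no-water, resolution.

    'Better than' the resolution cutoff is strict (<); unknown
    resolution is dropped (the kept corpus is explicitly X-ray
    high-resolution).  Mixed protein-nucleic complexes count as
    protein.
    """
    config = config or FilterConfig()
    if config.exclude_nonprotein and not meta.has_protein:
        return FilterDecision(False, "non-protein")
    if config.require_waters and meta.n_waters == 0:
        return FilterDecision(False, "no-water")
    if meta.resolution_A is None or meta.resolution_A >= config.resolution_cutoff_A:
        return FilterDecision(False, "resolution")
    return FilterDecision(True)


def filter_directory(
    paths: Iterable[str | Path] | str | Path,
    config: FilterConfig | None = None,
) -> tuple[FilterReport, list[Path]]:
    """Filter a directory (or explicit list) of PDB files.

    Files are processed in sorted order; unparseable files are logged
    and counted, never silently skipped.  Returns the report and the
    kept paths.
    """
    config = config or FilterConfig()
    if isinstance(paths, (str, Path)):
        path_list: Sequence[Path] = sorted(Path(paths).glob("*.pdb"))
    else:
        path_list = sorted(Path(p) for p in paths)
    report = FilterReport(n_input=len(path_list))
    kept: list[Path] = []
    for p in path_list:
        try:
            _, meta = read_structure(p)
        except (FormatError, FileNotFoundError) as exc:
            report.n_unparseable += 1
            report.decisions.append((str(p), f"unparseable: {exc}"))
            logger.warning("unparseable structure %s: %s", p, exc)
            continue
        decision = filter_structure(meta, config)
        if decision.keep:
            report.n_kept += 1
            report.decisions.append((str(p), "keep"))
            kept.append(p)
        else:
            attr = {
                "non-protein": "n_dropped_nonprotein",
                "no-water": "n_dropped_nowater",
                "resolution": "n_dropped_resolution",
            }[decision.reason]
            setattr(report, attr, getattr(report, attr) + 1)
            report.decisions.append((str(p), f"drop({decision.reason})"))
            logger.info("drop %s: %s", p, decision.reason)
    return report, kept
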