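"""Source-file acquisition with a retry-until-complete contract.

Seven sources feed the warehouse: the taxonomy dump, per-taxon batches
of nucleotide records, the Swiss-Prot DAT, the varsplic isoform FASTA,
the GO OBO file, the Pfam family table and the two SIFTS chain-mapping
TSVs.  The transfer mechanism is injectable (any callable
``transport(item, dest_path)``), which is what makes the retry contract
testable with scripted fakes and lets an offline configuration satisfy a
whole plan from a local fixture directory with zero transfers.

Acquisition retries each missing file up to ``max_attempts`` times;
partial files are discarded, never resumed, and a completed item is
never overwritten.
"""

from __future__ import annotations

import math
import shutil
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from .errors import AcquisitionError, ConfigurationError
from .taxonomy import TaxonSet

SOURCE_NAMES = (
    "taxonomy",
    "nucleotide",
    "swissprot",
    "varsplic",
    "go",
    "pfam",
    "sifts",
)

#: canonical local file names per source (nucleotide is batched separately)
SOURCE_FILES: dict[str, tuple[str, ...]] = {
    "taxonomy": ("names.dmp", "nodes.dmp"),
    "swissprot": ("swissprot.dat",),
    "varsplic": ("varsplic.fasta",),
    "go": ("go.obo",),
    "pfam": ("pfam_families.tsv",),
    "sifts": ("pdb_chain_uniprot.tsv", "pdb_chain_pfam.tsv"),
}

DEFAULT_BATCH_SIZE = 50
DEFAULT_MAX_ATTEMPTS = 5

Transport = Callable[["PlanItem", Path], None]


@dataclass
class PlanItem:
    source: str  # one of SOURCE_NAMES
    local_name: str
    dest: Path
    required: bool = True
    taxids: tuple[int, ...] = ()  # for nucleotide batches


@dataclass
class DownloadPlan:
    items: list[PlanItem]
    max_attempts: int = DEFAULT_MAX_ATTEMPTS
    completed: set[str] = field(default_factory=set)
    attempt_log: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def satisfied(self) -> bool:
        return all(
            (not item.required) or item.local_name in self.completed
            for item in self.items
        )

    @property
    def missing(self) -> list[str]:
        return [
            item.local_name
            for item in self.items
            if item.required and item.local_name not in self.completed
        ]

    def total_attempts(self) -> int:
        return len(self.attempt_log)


def _source_paths(config: dict) -> dict[str, str]:
    sources = config.get("sources")
    if not isinstance(sources, dict):
        raise ConfigurationError("configuration has no 'sources' mapping")
    missing = [name for name in SOURCE_NAMES if name not in sources]
    if missing:
        raise ConfigurationError(
            "configuration missing source(s): " + ", ".join(missing)
        )
    return {name: str(sources[name]) for name in SOURCE_NAMES}


def _is_remote(location: str) -> bool:
    return urllib.parse.urlparse(location).scheme in ("http", "https", "ftp")


def plan_downloads(
    organism: TaxonSet, config: dict, dest_dir: str | Path
) -> DownloadPlan:
    """Build the acquisition plan for every source.

    ``config`` maps each of the seven sources to a location (URL or local
    directory).  For a local nucleotide directory the plan lists the
    GenBank files actually present; for a remote one it lists one batch
    item per ``nucleotide_batch_size`` member taxids (the "sequence
    bins" that keep CDS extraction bounded).
    """
    dest_dir = Path(dest_dir)
    locations = _source_paths(config)
    batch_size = int(config.get("nucleotide_batch_size", DEFAULT_BATCH_SIZE))
    if batch_size < 1:
        raise ConfigurationError("nucleotide_batch_size must be >= 1")
    items: list[PlanItem] = []
    for source in SOURCE_NAMES:
        location = locations[source]
        remote = _is_remote(location)
        if source == "nucleotide":
            if remote:
                members = sorted(organism.member_taxids)
                n_batches = math.ceil(len(members) / batch_size) if members else 0
                for i in range(n_batches):
                    batch = tuple(members[i * batch_size : (i + 1) * batch_size])
                    name = f"nucleotide_batch_{i + 1:04d}.gbff"
                    items.append(
                        PlanItem(source, name, dest_dir / name, taxids=batch)
                    )
            else:
                for path in sorted(Path(location).glob("*.gbff")):
                    items.append(PlanItem(source, path.name, path))
            continue
        for name in SOURCE_FILES[source]:
            dest = dest_dir / name if remote else Path(location) / name
            items.append(PlanItem(source, name, dest))
    plan = DownloadPlan(items=items)
    # local files already in place satisfy their items with zero transfers
    for item in plan.items:
        if not _is_remote(locations[item.source]) and item.dest.exists():
            plan.completed.add(item.local_name)
    return plan


def fetch_with_retry(plan: DownloadPlan, transport: Transport) -> DownloadPlan:
    """Acquire every planned item, retrying failures up to ``max_attempts``.

    An item whose destination already exists with non-zero size is
    complete and costs zero transport calls.  A failed transfer's
    partial file is deleted before the next attempt.  Raises
    :class:`AcquisitionError` naming every required item still missing
    after the retry budget.
    """
    for item in plan.items:
        if item.local_name in plan.completed:
            continue
        if item.dest.exists() and item.dest.stat().st_size > 0:
            plan.completed.add(item.local_name)
            continue
        for attempt in range(1, plan.max_attempts + 1):
            try:
                item.dest.parent.mkdir(parents=True, exist_ok=True)
                transport(item, item.dest)
            except Exception as exc:  # noqa: BLE001 - transport is third-party code
                plan.attempt_log.append((item.local_name, attempt, f"failed: {exc}"))
                if item.dest.exists():
                    item.dest.unlink()  # discard partial file, never resume
                continue
            if item.dest.exists() and item.dest.stat().st_size > 0:
                plan.attempt_log.append((item.local_name, attempt, "ok"))
                plan.completed.add(item.local_name)
                break
            plan.attempt_log.append((item.local_name, attempt, "failed: empty file"))
    if plan.missing:
        raise AcquisitionError(plan.missing)
    return plan


def copy_transport(src_dir: str | Path) -> Transport:
    """Transport that copies files from a local directory (for mirroring fixtures)."""
    src = Path(src_dir)

    def _copy(item: PlanItem, dest: Path) -> None:
        origin = src / item.local_name
        if not origin.exists():
            raise FileNotFoundError(origin)
        shutil.copyfile(origin, dest)

    return _copy


def grouped_paths(plan: DownloadPlan) -> dict[str, list[Path]]:
    """Completed item destinations grouped by source, in plan order."""
    out: dict[str, list[Path]] = {name: [] for name in SOURCE_NAMES}
    for item in plan.items:
        if item.local_name in plan.completed:
            out[item.source].append(item.dest)
    return out
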