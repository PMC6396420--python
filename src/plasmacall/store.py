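"""Per-fragment evidence store.

The caller never touches reads directly: its sole read-level input is a table
of (site, allele, template length, pairing, qualities) rows, one per physical
cfDNA fragment per site.  The on-disk dialect is a gzip-compressed TSV plus a
JSON metadata sidecar, chosen to be diffable and language-agnostic; writes are
byte-deterministic (gzip mtime pinned to 0) so identical stores hash
identically.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path

STORE_SCHEMA_VERSION = 1
_COLUMNS = ("site_id", "allele", "tlen", "properly_paired", "base_quality", "map_quality", "fragment_id")

REF, ALT = "REF", "ALT"


class StoreSchemaError(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class FragmentObservation:
    """One cfDNA fragment's evidence at one site."""

    site_id: str
    allele: str  # "REF" or "ALT"
    tlen: int  # absolute template length; 0 only if unavailable
    properly_paired: bool
    base_quality: int
    map_quality: int
    fragment_id: str

    def __post_init__(self):
        if self.allele not in (REF, ALT):
            raise ValueError(f"allele must be REF or ALT, got {self.allele!r}")
        if self.tlen < 0:
            raise ValueError("tlen is an absolute length, must be >= 0")
        if self.tlen == 0 and self.properly_paired:
            raise ValueError("tlen=0 (unavailable) requires properly_paired=False")


class EvidenceStore:
    """Ordered mapping site_id -> list of FragmentObservation, with provenance."""

    def __init__(self, metadata: dict | None = None):
        self._obs: dict[str, list[FragmentObservation]] = {}
        self.metadata: dict = dict(metadata or {})

    def add(self, obs: FragmentObservation) -> None:
        self._obs.setdefault(obs.site_id, []).append(obs)

    def add_many(self, observations) -> None:
        for o in observations:
            self.add(o)

    def observations(self, site_id: str) -> list[FragmentObservation]:
        return self._obs.get(site_id, [])

    def site_ids(self) -> list[str]:
        return list(self._obs)

    def items(self):
        return self._obs.items()

    def depth(self, site_id: str) -> int:
        return len(self._obs.get(site_id, ()))

    @property
    def n_sites(self) -> int:
        return len(self._obs)

    @property
    def n_observations(self) -> int:
        return sum(len(v) for v in self._obs.values())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EvidenceStore)
            and self._obs == other._obs
            and self.metadata == other.metadata
        )

    def __repr__(self) -> str:
        return f"EvidenceStore({self.n_sites} sites, {self.n_observations} observations)"


def _meta_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_store(store: EvidenceStore, path) -> None:
    """Serialize a store to gzip TSV + JSON sidecar, deterministically."""
    path = Path(path)
    meta = {"store_schema_version": STORE_SCHEMA_VERSION, **store.metadata}
    with open(path, "wb") as raw:
        # mtime=0 and empty filename keep the gzip container byte-stable
        with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
            gz.write(("\t".join(_COLUMNS) + "\n").encode())
            for site_id, obs_list in store.items():
                for o in obs_list:
                    row = (
                        site_id,
                        o.allele,
                        str(o.tlen),
                        "1" if o.properly_paired else "0",
                        str(o.base_quality),
                        str(o.map_quality),
                        o.fragment_id,
                    )
                    gz.write(("\t".join(row) + "\n").encode())
    _meta_path(path).write_text(json.dumps(meta, indent=0, sort_keys=True) + "\n")


def read_store(path) -> EvidenceStore:
    """Read a store written by :func:`write_store` (lossless round trip)."""
    path = Path(path)
    meta_file = _meta_path(path)
    metadata: dict = {}
    if meta_file.exists():
        metadata = json.loads(meta_file.read_text())
        version = metadata.pop("store_schema_version", None)
        if version != STORE_SCHEMA_VERSION:
            raise StoreSchemaError(
                f"store schema version mismatch: file has {version}, "
                f"reader supports {STORE_SCHEMA_VERSION}"
            )
    store = EvidenceStore(metadata=metadata)
    with gzip.open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _COLUMNS:
            raise StoreSchemaError(f"unexpected store columns: {header}")
        for line in fh:
            site_id, allele, tlen, pp, bq, mq, frag = line.rstrip("\n").split("\t")
            store.add(
                FragmentObservation(
                    site_id=site_id,
                    allele=allele,
                    tlen=int(tlen),
                    properly_paired=pp == "1",
                    base_quality=int(bq),
                    map_quality=int(mq),
                    fragment_id=frag,
                )
            )
    return store
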