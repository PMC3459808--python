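"""Shared TSV/BED emitters for predicted sites and reports.

TSV columns carry 1-based inclusive coordinates (matching the genomic
intervals printed throughout); BED output is 0-based half-open.  Every table
starts with a comment header recording the tool version and a hash of the
configuration that produced it, so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .duplex import DuplexSite

__all__ = ["config_hash", "write_sites_tsv", "write_sites_bed", "write_frame_tsv"]


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: dict | None) -> str:
    h = config_hash(config or {})
    return f"# mirsitescan {__version__} config={h}\n"


def sites_to_frame(sites: list[DuplexSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append(
            {
                "program": s.program,
                "mirna": s.mirna_id,
                "utr": s.utr_id,
                "local_start": s.local_start,
                "local_end": s.local_end,
                "chrom": s.genomic.chrom if s.genomic else "",
                "g_start": s.genomic.start if s.genomic else "",
                "g_end": s.genomic.end if s.genomic else "",
                "strand": s.genomic.strand if s.genomic else "",
                "energy_kcal_mol": s.energy,
                "paired": s.paired,
                "score": "" if s.score is None else s.score,
                "pvalue": "" if s.pvalue is None else s.pvalue,
                "pairing": s.pairing,
            }
        )
    return pd.DataFrame(rows)


def write_sites_tsv(path: str | Path, sites: list[DuplexSite],
                    config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        sites_to_frame(sites).to_csv(fh, sep="\t", index=False)


def write_sites_bed(path: str | Path, sites: list[DuplexSite],
                    config: dict | None = None) -> None:
    """Genomic BED6 (0-based half-open) of sites that carry an interval."""
    with open(path, "w") as fh:
        fh.write(_header(config))
        for s in sites:
            if s.genomic is None:
                continue
            name = f"{s.mirna_id}:{s.program}"
            fh.write(
                f"{s.genomic.chrom}\t{s.genomic.start - 1}\t{s.genomic.end}"
                f"\t{name}\t{s.energy}\t{s.genomic.strand}\n"
            )


def write_frame_tsv(path: str | Path, frame: pd.DataFrame,
                    config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        frame.to_csv(fh, sep="\t", index=False)
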