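"""Column-oriented container for aligned reads.

The estimators in this package only need a handful of alignment fields
(reference, position, FLAG, MAPQ, aligned length, and — for repeat
counting — the read sequence), so reads are held as columns of a pandas
DataFrame rather than as per-read objects.  Sets round-trip losslessly
through SAM (via pysam) and through a plain tab-delimited mirror.

Simulated reads additionally carry a truth-origin tag (``origin``
column, SAM aux tag ``XO``) naming the compartment the read was drawn
from (nuclear, mito, numt, contaminant, telomeric).  Estimators never
consult this column; it exists only so tests can score estimates
against ground truth.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

#: canonical column order of the underlying frame
COLUMNS = ("name", "flag", "ref", "pos", "mapq", "length", "seq", "origin")

#: SAM FLAG bits used throughout
FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800


class AlignedReadSet:
    """A set of aligned reads backed by a column-oriented frame.

    Parameters
    ----------
    frame:
        DataFrame with (at least) the columns in :data:`COLUMNS`.
        ``pos`` is the 0-based leftmost aligned position (−1 for
        unmapped reads, whose ``ref`` is ``"*"``); ``length`` is the
        aligned reference span in bp; ``seq`` and ``origin`` may be
        missing (``pd.NA``).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"read frame missing columns: {sorted(missing)}")
        self.frame = frame.loc[:, list(COLUMNS)].reset_index(drop=True)

    # -- construction ------------------------------------------------

    @classmethod
    def from_columns(cls, *, name, flag, ref, pos, mapq, length,
                     seq=None, origin=None) -> "AlignedReadSet":
        n = len(pos)
        frame = pd.DataFrame({
            "name": np.asarray(name, dtype=object),
            "flag": np.asarray(flag, dtype=np.int64),
            "ref": np.asarray(ref, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "mapq": np.asarray(mapq, dtype=np.int64),
            "length": np.asarray(length, dtype=np.int64),
            "seq": pd.array([pd.NA] * n, dtype=object) if seq is None
            else pd.array(list(seq), dtype=object),
            "origin": pd.array([pd.NA] * n, dtype=object) if origin is None
            else pd.array(list(origin), dtype=object),
        })
        return cls(frame)

    @classmethod
    def concat(cls, sets: Iterable["AlignedReadSet"]) -> "AlignedReadSet":
        frames = [s.frame for s in sets]
        if not frames:
            return cls.empty()
        return cls(pd.concat(frames, ignore_index=True))

    @classmethod
    def empty(cls) -> "AlignedReadSet":
        return cls.from_columns(name=[], flag=[], ref=[], pos=[], mapq=[],
                                length=[])

    # -- basics ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        refs = self.frame["ref"].value_counts().to_dict()
        return f"AlignedReadSet(n={len(self)}, refs={refs})"

    def subset(self, mask) -> "AlignedReadSet":
        """Return the reads selected by a boolean mask (copy)."""
        mask = np.asarray(mask, dtype=bool)
        return AlignedReadSet(self.frame.loc[mask])

    def on_reference(self, ref: str, mapped_only: bool = True) -> "AlignedReadSet":
        mask = (self.frame["ref"] == ref).to_numpy()
        if mapped_only:
            mask &= (self.frame["flag"].to_numpy() & FLAG_UNMAPPED) == 0
        return self.subset(mask)

    # -- TSV mirror --------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the documented tab-delimited mirror (header + one row
        per read, columns as :data:`COLUMNS`; empty seq/origin fields
        denote missing values)."""
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AlignedReadSet":
        frame = pd.read_csv(
            path, sep="\t",
            dtype={"name": object, "ref": object, "seq": object,
                   "origin": object},
        )
        for col in ("seq", "origin"):
            if col not in frame:
                frame[col] = pd.NA
            frame[col] = frame[col].where(frame[col].notna(), pd.NA)
        return cls(frame)

    # -- SAM ---------------------------------------------------------

    def to_sam(self, path, references: Mapping[str, int]) -> None:
        """Write as (uncompressed) SAM.

        ``references`` maps reference names to lengths for the header;
        every mapped read's reference must appear in it.
        """
        header = pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": int(length)}
                   for name, length in references.items()],
        })
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for row in self.frame.itertuples(index=False):
                a = pysam.AlignedSegment(header)
                a.query_name = str(row.name)
                a.flag = int(row.flag)
                a.mapping_quality = int(row.mapq)
                mapped = (row.flag & FLAG_UNMAPPED) == 0
                if mapped:
                    tid = header.get_tid(row.ref)
                    if tid < 0:
                        raise ValueError(
                            f"reference {row.ref!r} absent from header")
                    a.reference_id = tid
                    a.reference_start = int(row.pos)
                    a.cigartuples = [(0, int(row.length))]
                if row.seq is not pd.NA and isinstance(row.seq, str):
                    if mapped and len(row.seq) != int(row.length):
                        # aligned span and stored sequence must agree
                        raise ValueError("sequence length != aligned length")
                    a.query_sequence = row.seq
                if row.origin is not pd.NA and isinstance(row.origin, str):
                    a.set_tag("XO", row.origin)
                out.write(a)

    @classmethod
    def from_sam(cls, path) -> "AlignedReadSet":
        names, flags, refs, poss, mapqs, lengths, seqs, origins = \
            [], [], [], [], [], [], [], []
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
            for a in handle.fetch(until_eof=True):
                names.append(a.query_name)
                flags.append(a.flag)
                mapped = not a.is_unmapped
                refs.append(a.reference_name if mapped else "*")
                poss.append(a.reference_start if mapped else -1)
                mapqs.append(a.mapping_quality)
                if mapped and a.reference_length:
                    lengths.append(a.reference_length)
                else:
                    lengths.append(len(a.query_sequence or ""))
                seqs.append(a.query_sequence if a.query_sequence else pd.NA)
                origins.append(a.get_tag("XO") if a.has_tag("XO") else pd.NA)
        return cls.from_columns(name=names, flag=flags, ref=refs, pos=poss,
                                mapq=mapqs, length=lengths, seq=seqs,
                                origin=origins)

    # -- convenience for loading either format -----------------------

    @classmethod
    def load(cls, path) -> "AlignedReadSet":
        """Load from ``.sam`` or ``.tsv`` based on the file suffix."""
        p = str(path)
        if p.endswith(".sam"):
            return cls.from_sam(p)
        return cls.from_tsv(p)
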