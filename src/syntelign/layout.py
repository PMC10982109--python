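"""Automatic and manual placement of sequence tracks.

The automatic position adjustment mirrors how a person aligns a stack of
genome tracks by hand: the highest-scoring HSP between the first two
sequences (in guide-tree order) is placed at the display center; every
subsequent sequence is anchored to its predecessor by their highest-scoring
HSP — inverted when the anchor is on the opposite strand, and circularly
permuted (for sequences flagged circular) so that track midpoints line up
vertically, with the anchor alignment taking precedence and the rotation
absorbing the remainder. Sequences with no HSP to their predecessor keep
the identity transform and a warning is logged.

This single-anchor strategy can shift the ends of two genomes that are
similar end to end — the anchor, not the ends, is what gets aligned — so
manual edits (`apply_manual`) remain available for refinement.

Display coordinates: a transform applies circular rotation first, then
inversion (pos -> length - pos), then the offset shift; all arithmetic is
exact integer arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .pairalign import HitSet, Hsp
from .seqio import SeqRecord

logger = logging.getLogger(__name__)


@dataclass
class LayoutTransform:
    """Per-sequence placement: rotation (circular only), inversion, offset."""

    seq_id: str
    length: int
    offset: int = 0
    inverted: bool = False
    rotation: int = 0  # original bp position drawn at track start; 0 if linear

    def __post_init__(self) -> None:
        if not (0 <= self.rotation < max(self.length, 1)):
            raise ValueError(
                f"rotation {self.rotation} out of range for {self.seq_id!r} "
                f"(length {self.length})"
            )

    @property
    def display_length(self) -> int:
        return self.length

    def map_coord(self, pos: int) -> int:
        """Display coordinate of a forward-strand position (0 <= pos <= length)."""
        if not (0 <= pos <= self.length):
            raise ValueError(
                f"position {pos} out of range [0, {self.length}] for {self.seq_id!r}"
            )
        x = pos
        if self.rotation:
            x = (x - self.rotation) % self.length
        if self.inverted:
            x = self.length - x
        return x + self.offset

    def map_interval(self, start: int, end: int) -> tuple[int, int]:
        """Display interval of [start, end); endpoints sorted after inversion.

        For rotated circular sequences an interval can wrap around the track
        edge; the dominant (longer) piece's endpoints are returned.
        """
        if self.rotation:
            a = (start - self.rotation) % self.length
            b = a + (end - start)
            if b > self.length:  # wraps: keep the longer piece
                left = self.length - a  # piece at track end
                right = b - self.length  # piece at track start
                if left >= right:
                    a, b = a, self.length
                else:
                    a, b = 0, right
        else:
            a, b = start, end
        if self.inverted:
            a, b = self.length - b, self.length - a
        return a + self.offset, b + self.offset


@dataclass
class Layout:
    """Ordered (record, transform) pairs, one per displayed sequence."""

    items: list[tuple[SeqRecord, LayoutTransform]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    @property
    def ids(self) -> list[str]:
        return [r.id for r, _ in self.items]

    def transform(self, seq_id: str) -> LayoutTransform:
        for r, t in self.items:
            if r.id == seq_id:
                return t
        raise KeyError(seq_id)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("seq_id\toffset\tinverted\trotation\n")
            for _, t in self.items:
                fh.write(f"{t.seq_id}\t{t.offset}\t{int(t.inverted)}\t{t.rotation}\n")


def map_coord(t: LayoutTransform, pos: int) -> int:
    return t.map_coord(pos)


def _midpoint(start: int, end: int) -> int:
    return (start + end) // 2


def _top_hsp(hsps: list[Hsp]) -> Hsp | None:
    """Highest raw score; ties broken by longest span, then smallest coords."""
    if not hsps:
        return None
    return min(
        hsps,
        key=lambda h: (-h.raw_score, -(h.qend - h.qstart), h.qstart, h.sstart),
    )


def auto_layout(order: list[SeqRecord], hits: HitSet) -> Layout:
    """Anchor-based automatic layout of sequences in display order.

    The top HSP of the first pair is centered at display coordinate 0; each
    later sequence is inverted to make its anchor co-directional with the
    (already transformed) predecessor, circularly permuted (if flagged
    circular) so its track midpoint sits under the predecessor's, and
    shifted so the anchor midpoints align vertically.
    """
    if len(order) < 2:
        raise ValueError("auto layout needs at least two sequences")
    transforms: list[LayoutTransform] = [
        LayoutTransform(seq_id=r.id, length=r.length) for r in order
    ]

    # (1) center the top HSP of the first pair: the first sequence is shifted
    # so the anchor's query midpoint lands on display coordinate 0, then the
    # second sequence is aligned to it the same way all later ones are.
    first_anchor = _top_hsp(hits.get(order[0].id, order[1].id))
    if first_anchor is not None:
        t0 = transforms[0]
        qa, qb = t0.map_interval(first_anchor.qstart, first_anchor.qend)
        t0.offset = -_midpoint(qa, qb)

    # (2) align each sequence k to its predecessor by their top HSP
    for k in range(1, len(order)):
        prev, cur = order[k - 1], order[k]
        tprev, tcur = transforms[k - 1], transforms[k]
        anchor = first_anchor if k == 1 else _top_hsp(hits.get(prev.id, cur.id))
        if anchor is None:
            logger.warning(
                "no HSP between %s and %s; %s keeps the identity transform",
                prev.id, cur.id, cur.id,
            )
            continue
        # invert so the anchor is co-directional after both transforms
        tcur.inverted = anchor.subject_reversed ^ tprev.inverted
        qa, qb = tprev.map_interval(anchor.qstart, anchor.qend)
        target = _midpoint(qa, qb)
        if cur.circular:
            # center the track under the predecessor's track midpoint …
            prev_mid = tprev.offset + prev.length // 2
            tcur.offset = prev_mid - cur.length // 2
            # … and let the rotation absorb the anchor alignment
            smid = _midpoint(anchor.sstart, anchor.send)
            want = target - tcur.offset  # pre-offset display position of anchor mid
            if tcur.inverted:
                want = cur.length - want
            tcur.rotation = (smid - want) % cur.length
        else:
            sa, sb = tcur.map_interval(anchor.sstart, anchor.send)
            tcur.offset = target - _midpoint(sa, sb)
    return Layout(items=list(zip(order, transforms)))


@dataclass
class ManualEdit:
    """One edit: set_offset / toggle_invert / set_rotation / move_to_index /
    delete / duplicate, addressed by sequence id."""

    seq_id: str
    set_offset: int | None = None
    toggle_invert: bool = False
    set_rotation: int | None = None
    move_to_index: int | None = None
    delete: bool = False
    duplicate: bool = False


def apply_manual(layout: Layout, edits: list[ManualEdit]) -> Layout:
    """Apply manual edits in list order, returning a new Layout.

    Duplication inserts a copy directly after the original with an id
    suffixed ``_copy1`` (``_copy2``, … on repeated duplication).
    """
    items = list(layout.items)
    for e in edits:
        idx = next((i for i, (r, _) in enumerate(items) if r.id == e.seq_id), None)
        if idx is None:
            raise KeyError(f"unknown sequence id {e.seq_id!r}")
        rec, t = items[idx]
        if e.set_offset is not None:
            t = replace(t, offset=e.set_offset)
        if e.toggle_invert:
            t = replace(t, inverted=not t.inverted)
        if e.set_rotation is not None:
            if not rec.circular:
                raise ValueError(f"rotation on non-circular sequence {rec.id!r}")
            t = replace(t, rotation=e.set_rotation % rec.length)
        items[idx] = (rec, t)
        if e.delete:
            items.pop(idx)
            continue
        if e.duplicate:
            existing = set(r.id for r, _ in items)
            n = 1
            while f"{rec.id}_copy{n}" in existing:
                n += 1
            new_id = f"{rec.id}_copy{n}"
            new_rec = SeqRecord(
                id=new_id, sequence=rec.sequence, circular=rec.circular,
                genes=list(rec.genes),
            )
            items.insert(idx + 1, (new_rec, replace(t, seq_id=new_id)))
        if e.move_to_index is not None:
            cur = next(i for i, (r, _) in enumerate(items) if r.id == e.seq_id)
            item = items.pop(cur)
            items.insert(max(0, min(e.move_to_index, len(items))), item)
    return Layout(items=items)


def read_layout_tsv(path, records: list[SeqRecord]) -> Layout:
    """Load a layout from its TSV serialization (seq_id, offset, inverted, rotation)."""
    by_id = {r.id: r for r in records}
    items = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("seq_id"):
            raise ValueError(f"{path}: missing layout header")
        for line in fh:
            if not line.strip():
                continue
            sid, off, inv, rot = line.rstrip("\n").split("\t")
            if sid not in by_id:
                raise KeyError(f"{path}: unknown sequence id {sid!r}")
            rec = by_id[sid]
            items.append(
                (rec, LayoutTransform(seq_id=sid, length=rec.length,
                                      offset=int(off), inverted=bool(int(inv)),
                                      rotation=int(rot)))
            )
    return Layout(items=items)
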