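"""Tiling a ligand sequence with scanning windows and motif extensions.

The scanning protocol covers a chain of length ``L`` with fixed windows of
100 residues overlapping by at least 30, so that any binding motif of up to
31 residues is guaranteed to lie entirely inside at least one window.  The
final window is re-anchored to the chain end rather than shortened, keeping
every fragment at the full window length for the predictor; the resulting
effective overlap with its predecessor may exceed the minimum and is never
reduced below it.

Motif-centered extensions grow a known motif by a total of ``extra``
residues split evenly across both sides; residues blocked by a chain
terminus are redistributed to the other side.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats_io import ChainSequence, Region

DEFAULT_WINDOW = 100
DEFAULT_OVERLAP = 30


@dataclass
class FragmentSet:
    """The fragments tiling (or extending within) a parent chain."""

    parent: ChainSequence
    fragments: list  # list[Region], sorted by start
    kind: str  # scan | extension | delimited | full_length
    window_length: int = DEFAULT_WINDOW
    min_overlap: int = DEFAULT_OVERLAP

    def __post_init__(self) -> None:
        L = len(self.parent)
        starts = [f.start for f in self.fragments]
        if starts != sorted(starts):
            raise ValueError("fragments must be sorted by start")
        for f in self.fragments:
            f.validate_on(L)
        if self.kind == "scan":
            if self.fragments[0].start != 1 or self.fragments[-1].end != L:
                raise ValueError("scan fragments must span the whole parent")
            for a, b in zip(self.fragments, self.fragments[1:]):
                if a.end - b.start + 1 < self.min_overlap:
                    raise ValueError("consecutive scan fragments must overlap")
            if any(len(f) > self.window_length for f in self.fragments):
                raise ValueError("scan fragment exceeds window length")

    def __len__(self) -> int:
        return len(self.fragments)

    def sequences(self) -> list:
        return [
            self.parent.sequence[f.start - 1 : f.end] for f in self.fragments
        ]


def make_scan_windows(
    L: int, window: int = DEFAULT_WINDOW, overlap: int = DEFAULT_OVERLAP,
    parent: ChainSequence | None = None,
) -> FragmentSet:
    """Scanning windows over a chain of length ``L``.

    A chain no longer than the window yields the single fragment ``(1, L)``.
    Otherwise windows start at 1 with stride ``window - overlap`` and the
    final window is re-anchored to end exactly at ``L``.
    """
    if L < 1:
        raise ValueError("parent length must be >= 1")
    if overlap >= window:
        raise ValueError(f"overlap {overlap} must be < window {window}")
    if parent is None:
        parent = ChainSequence("synthetic", "A", "A" * L)
    if len(parent) != L:
        raise ValueError("parent length mismatch")
    if L <= window:
        frags = [Region(1, L)]
    else:
        stride = window - overlap
        n = -(-(L - window) // stride) + 1  # ceil division
        frags = [Region(1 + i * stride, i * stride + window) for i in range(n - 1)]
        frags.append(Region(L - window + 1, L))
    return FragmentSet(
        parent=parent, fragments=frags, kind="scan",
        window_length=window, min_overlap=overlap,
    )


def extend_motif(motif: Region, L: int, extra: int) -> Region:
    """Grow ``motif`` by a total of ``extra`` residues within ``[1, L]``.

    The addition is split floor(extra/2) left / remainder right; whatever a
    chain terminus blocks is pushed to the other side. The result never
    shrinks and is the identity when ``extra`` is 0 or the motif already
    spans the chain.
    """
    motif.validate_on(L)
    if extra < 0:
        raise ValueError("extra must be >= 0")
    total = min(extra, L - len(motif))
    want_left = extra // 2
    want_right = extra - want_left
    cap_left = motif.start - 1
    cap_right = L - motif.end
    left = min(want_left, cap_left)
    right = min(want_right + (want_left - left), cap_right)
    left = min(left + (want_right + (want_left - left) - right), cap_left)
    assert left + right == total
    return Region(motif.start - left, motif.end + right)


def overlaps_motif(fragment: Region, motif: Region) -> tuple[bool, int]:
    """Whether a fragment touches the motif, and by how many residues."""
    n = fragment.intersection_length(motif)
    return n >= 1, n


def containment_guarantee(L: int, window: int, overlap: int, m: int) -> bool:
    """True iff every length-``m`` interval in ``[1, L]`` fits in one window."""
    if m < 1:
        raise ValueError("motif length must be >= 1")
    if m > L:
        return True  # vacuous: no placement exists
    windows = make_scan_windows(L, window, overlap).fragments
    for start in range(1, L - m + 2):
        placement = Region(start, start + m - 1)
        if not any(w.contains(placement) for w in windows):
            return False
    return True
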