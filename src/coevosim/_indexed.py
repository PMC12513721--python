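"""Set with O(1) uniform random choice, used for cells and carrier sets."""

from __future__ import annotations


class IndexedSet:
    """A set of hashables supporting O(1) add/discard/uniform-choice."""

    __slots__ = ("_items", "_pos")

    def __init__(self, iterable=()):
        self._items = []
        self._pos = {}
        for x in iterable:
            self.add(x)

    def add(self, x) -> None:
        if x not in self._pos:
            self._pos[x] = len(self._items)
            self._items.append(x)

    def discard(self, x) -> None:
        pos = self._pos.pop(x, None)
        if pos is None:
            return
        last = self._items.pop()
        if pos < len(self._items):
            self._items[pos] = last
            self._pos[last] = pos

    def choose(self, rng):
        """Uniform random element (numpy Generator)."""
        return self._items[int(rng.integers(len(self._items)))]

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, x) -> bool:
        return x in self._pos

    def __iter__(self):
        return iter(self._items)

    def __repr__(self) -> str:  # pragma: no cover
        return f"IndexedSet({self._items!r})"
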