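"""A minimal character trie.

Used to hold the precomputed stop-gain SNV index. Keys are strings whose
lexicographic order is meaningful (variant keys use zero-padded positions so
that lexicographic order equals genomic order); :meth:`Trie.items` therefore
iterates keys in sorted order without an explicit sort.
"""

from __future__ import annotations

from typing import Any, Iterator

_VALUE = "\0"  # sentinel slot; never a key character


class Trie:
    """Mutable mapping from strings to arbitrary payloads, stored as a trie."""

    __slots__ = ("_root", "_size")

    def __init__(self) -> None:
        self._root: dict = {}
        self._size = 0

    def __len__(self) -> int:
        return self._size

    def __setitem__(self, key: str, value: Any) -> None:
        node = self._root
        for ch in key:
            node = node.setdefault(ch, {})
        if _VALUE not in node:
            self._size += 1
        node[_VALUE] = value

    def get(self, key: str, default: Any = None) -> Any:
        node = self._root
        for ch in key:
            node = node.get(ch)
            if node is None:
                return default
        return node.get(_VALUE, default)

    def __contains__(self, key: str) -> bool:
        sentinel = object()
        return self.get(key, sentinel) is not sentinel

    def items(self) -> Iterator[tuple[str, Any]]:
        """Yield (key, value) pairs in lexicographic key order."""
        stack: list[tuple[str, dict]] = [("", self._root)]
        while stack:
            prefix, node = stack.pop()
            if _VALUE in node:
                yield prefix, node[_VALUE]
            for ch in sorted((c for c in node if c != _VALUE), reverse=True):
                stack.append((prefix + ch, node[ch]))

    def keys_with_prefix(self, prefix: str) -> Iterator[str]:
        node = self._root
        for ch in prefix:
            node = node.get(ch)
            if node is None:
                return
        stack = [(prefix, node)]
        while stack:
            pfx, nd = stack.pop()
            if _VALUE in nd:
                yield pfx
            for ch in sorted((c for c in nd if c != _VALUE), reverse=True):
                stack.append((pfx + ch, nd[ch]))
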