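"""Shared argument checking helpers."""

from __future__ import annotations

from collections.abc import Iterable

_AXIS_OF = {"X": 0, "Y": 1, "Z": 2, "x": 0, "y": 1, "z": 2}


def axes_of(subset: str | Iterable[str]) -> tuple[int, ...]:
    """Map a variable subset like ``"XZ"`` or ``("X", "Z")`` to tensor axes.

    Axes are returned sorted and duplicates are rejected.
    """
    names = list(subset)
    axes = []
    for name in names:
        if name not in _AXIS_OF:
            raise ValueError(f"unknown variable {name!r}; expected X, Y or Z")
        axes.append(_AXIS_OF[name])
    if len(set(axes)) != len(axes):
        raise ValueError(f"duplicate variables in subset {subset!r}")
    return tuple(sorted(axes))
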