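"""Microraft grid addressing.

Each 100x100 um microraft is addressed by a four-character alphanumeric
Raft ID built from its (row, col) grid indices. Both axes use the same
two-character encoding: index ``i`` maps to letter ``'A' + i // 10`` and a
display digit cycling ``1..9, 0`` (so index 0 -> "A1", 9 -> "A0",
10 -> "B1"). The scheme is invertible for indices 0..259 per axis and is
the stable external contract for pick lists and sequencing well names.
"""

from __future__ import annotations

_AXIS_MAX = 260


def encode_axis(i: int) -> str:
    """Two-character code for one grid axis index."""
    if not 0 <= i < _AXIS_MAX:
        raise ValueError(f"grid index {i} outside encodable range 0..{_AXIS_MAX - 1}")
    letter = chr(ord("A") + i // 10)
    digit = (i % 10 + 1) % 10  # 1..9 then 0 for the tenth slot
    return f"{letter}{digit}"


def decode_axis(code: str) -> int:
    if len(code) != 2 or not code[0].isalpha() or not code[1].isdigit():
        raise ValueError(f"malformed axis code {code!r}")
    block = ord(code[0].upper()) - ord("A")
    digit = int(code[1])
    offset = (digit - 1) % 10
    return block * 10 + offset


def encode_raft_id(row: int, col: int) -> str:
    """Four-character Raft ID; (0, 0) -> 'A1A1'."""
    return encode_axis(row) + encode_axis(col)


def decode_raft_id(raft_id: str) -> tuple[int, int]:
    """Inverse of :func:`encode_raft_id`."""
    if len(raft_id) != 4:
        raise ValueError(f"Raft ID must be 4 characters, got {raft_id!r}")
    return decode_axis(raft_id[:2]), decode_axis(raft_id[2:])
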