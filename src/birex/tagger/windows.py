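"""Sliding-window splitting for documents longer than the encoder budget.

Each window carries ``k`` tokens of left/right context that contextualise
but are excluded from the final label prediction; the kept prediction
ranges partition the token indices exactly once.  Stride is
``window - 2k``; the first/last windows truncate context at the document
edges, and a document that fits in one window is predicted whole.
"""

from __future__ import annotations

from dataclasses import dataclass


class WindowConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Window:
    start: int  # token range [start, end) fed to the encoder
    end: int
    predict_start: int  # sub-range whose predictions are kept
    predict_end: int

    @property
    def left_context(self) -> int:
        return self.predict_start - self.start

    @property
    def right_context(self) -> int:
        return self.end - self.predict_end


def make_windows(n_tokens: int, window: int = 512, k: int = 32) -> list[Window]:
    if k < 0 or window <= 2 * k:
        raise WindowConfigError(f"need window > 2k >= 0, got window={window}, k={k}")
    if n_tokens <= 0:
        return []
    if n_tokens <= window:
        return [Window(0, n_tokens, 0, n_tokens)]
    stride = window - 2 * k
    out = []
    p = 0
    while p < n_tokens:
        p_end = min(p + stride, n_tokens)
        start = max(0, p - k)
        end = min(n_tokens, p_end + k)
        out.append(Window(start, end, p, p_end))
        p = p_end
    return out
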