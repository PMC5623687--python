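"""Independent straight-line interpreter of the locking rules.

Written directly from the six state descriptions as a window-consuming
while-loop, deliberately structured differently from the production
implementation, to serve as an equivalence oracle on random streams.
"""

from collections import Counter


def _majority_latest(buf):
    counts = Counter(buf)
    top = max(counts.values())
    for cls in reversed(buf):
        if counts[cls] == top:
            return cls
    raise AssertionError("unreachable")


def reference_postprocess(
    detector,
    oco,
    onset,
    offset_for,
    decision_window=6,
    unlock_grace=3,
    min_rest=3,
):
    """Emit (outputs, states) per window by literally walking States 1-6.

    ``offset_for`` maps a decision class to its offset threshold (a plain
    callable; constant for the equal-threshold regime).
    """
    n = len(oco)
    out, states = [], []
    mode = "REST"
    buf = []
    dec = None
    ngrace = 0
    below = 0
    i = 0
    while i < n:
        x, c = detector[i], oco[i]
        if mode == "REST":
            if x < onset:
                out.append("NM")
                states.append(1)
                i += 1
            else:
                mode, buf = "DECIDE", []
        elif mode == "DECIDE":
            if x < onset:
                out.append("NM")
                states.append(3)
                mode = "REST"
                i += 1
            else:
                out.append(c)
                states.append(2)
                if c != "NM":
                    buf.append(c)
                    if len(buf) == decision_window:
                        dec = _majority_latest(buf)
                        mode = "LOCK"
                i += 1
        elif mode == "LOCK":
            if x >= offset_for(dec):
                out.append(dec)
                states.append(4)
                i += 1
            elif x >= onset:
                mode, ngrace = "UNLOCK", 0
            else:
                mode, below = "HOLDREST", 0
        elif mode == "UNLOCK":
            if x < onset:
                mode, below = "HOLDREST", 0
            elif ngrace >= unlock_grace:
                mode, buf = "DECIDE", []
            elif x >= offset_for(dec):
                mode = "LOCK"
            else:
                out.append("NM")
                states.append(5)
                ngrace += 1
                i += 1
        else:  # HOLDREST: enforced rest before the next decision stage
            out.append("NM")
            states.append(6)
            below = below + 1 if x < onset else 0
            if below >= min_rest:
                mode = "REST"
            i += 1
    return out, states
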