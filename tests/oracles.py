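"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def flood_fill_components(binary):
    """8-connected labelling by explicit stack-based flood fill."""
    binary = np.asarray(binary, dtype=bool)
    lab = np.zeros(binary.shape, dtype=int)
    nxt = 0
    for sy in range(binary.shape[0]):
        for sx in range(binary.shape[1]):
            if binary[sy, sx] and lab[sy, sx] == 0:
                nxt += 1
                stack = [(sy, sx)]
                lab[sy, sx] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx_ = y + dy, x + dx
                            if (
                                0 <= ny < binary.shape[0]
                                and 0 <= nx_ < binary.shape[1]
                                and binary[ny, nx_]
                                and lab[ny, nx_] == 0
                            ):
                                lab[ny, nx_] = nxt
                                stack.append((ny, nx_))
    return lab, nxt
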