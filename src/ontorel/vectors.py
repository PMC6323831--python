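"""Reading and writing pre-trained word vectors in the textual word2vec format.

The format is a header line ``<count> <dim>`` followed by one line per
token: the token then ``dim`` whitespace-separated floats.
"""

from __future__ import annotations

import numpy as np

__all__ = ["load_word2vec_text", "save_word2vec_text"]


def load_word2vec_text(path) -> tuple[list[str], np.ndarray]:
    """Return (tokens, matrix of shape (count, dim)) from a text vector file."""
    with open(path) as fh:
        header = fh.readline().split()
        count, dim = int(header[0]), int(header[1])
        tokens, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) < dim + 1:
                continue
            tokens.append(parts[0])
            rows.append(np.asarray(parts[1 : dim + 1], dtype=np.float64))
    if len(tokens) != count:
        raise ValueError(f"header promises {count} vectors, file has {len(tokens)}")
    return tokens, np.vstack(rows) if rows else np.zeros((0, dim))


def save_word2vec_text(tokens: list[str], matrix: np.ndarray, path) -> None:
    if len(tokens) != matrix.shape[0]:
        raise ValueError("token count and matrix rows differ")
    with open(path, "w") as fh:
        fh.write(f"{len(tokens)} {matrix.shape[1]}\n")
        for tok, row in zip(tokens, matrix):
            fh.write(tok + " " + " ".join(f"{x:.8g}" for x in row) + "\n")
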