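"""Reading and writing molecule lists.

Plain text holds one SMILES per line; CSV tables carry a ``smiles`` column
plus optional numeric property columns for conditional training.
"""

from __future__ import annotations

import pandas as pd


def read_smiles(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_smiles(path, smiles_list) -> None:
    with open(path, "w") as fh:
        for s in smiles_list:
            fh.write(("" if s is None else s) + "\n")


def read_decode_results(path) -> list:
    """Like :func:`read_smiles` but blank lines are kept as ``None`` —
    the on-disk form of a failed decode from ``sample``/``optimize``."""
    with open(path) as fh:
        return [line.strip() or None for line in fh.read().splitlines()]


def read_table(path) -> pd.DataFrame:
    """SMILES file or CSV -> DataFrame with a ``smiles`` column."""
    path = str(path)
    if path.endswith(".csv"):
        frame = pd.read_csv(path)
        if "smiles" not in frame.columns:
            raise ValueError(f"{path} has no 'smiles' column")
        return frame
    return pd.DataFrame({"smiles": read_smiles(path)})


def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)
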