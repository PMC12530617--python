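"""Bundle of everything a trained diffusion model needs to generate:
vocabulary, noise schedule, denoiser weights, graph size and (for
conditional models) the property name and standardization statistics.

A saved checkpoint is a single ``.npz`` holding the parameter arrays plus a
JSON metadata blob, sufficient to resume sampling with no other inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .denoiser import DenoiserConfig, GraphTransformerDenoiser
from .mol_graph import Vocabulary
from .noise import NoiseSchedule


@dataclass
class MolecularDiffusion:
    vocab: Vocabulary
    schedule: NoiseSchedule
    denoiser: GraphTransformerDenoiser
    n: int  # fixed graph size
    conditional: bool = False
    condition_name: str | None = None
    cond_mean: float = 0.0
    cond_std: float = 1.0

    def standardize(self, value: float) -> float:
        return (value - self.cond_mean) / self.cond_std

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "vocab": {
                "atom_types": list(self.vocab.atom_types),
                "charge_types": [
                    c if isinstance(c, str) else int(c) for c in self.vocab.charge_types
                ],
            },
            "schedule": self.schedule.to_config(),
            "denoiser": self.denoiser.config_dict(),
            "n": self.n,
            "conditional": self.conditional,
            "condition_name": self.condition_name,
            "cond_mean": self.cond_mean,
            "cond_std": self.cond_std,
        }
        params = {k: v.data for k, v in self.denoiser.named_params().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **params)

    @classmethod
    def load(cls, path) -> "MolecularDiffusion":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            params = {k: archive[k] for k in archive.files if k != "__meta__"}
        vocab = Vocabulary(
            atom_types=tuple(meta["vocab"]["atom_types"]),
            charge_types=tuple(meta["vocab"]["charge_types"]),
        )
        schedule = NoiseSchedule.from_config(meta["schedule"])
        denoiser = GraphTransformerDenoiser(
            vocab,
            DenoiserConfig(**meta["denoiser"]),
            T=schedule.T,
            conditional=meta["conditional"],
        )
        denoiser.load_params(params)
        return cls(
            vocab=vocab,
            schedule=schedule,
            denoiser=denoiser,
            n=meta["n"],
            conditional=meta["conditional"],
            condition_name=meta["condition_name"],
            cond_mean=meta["cond_mean"],
            cond_std=meta["cond_std"],
        )
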