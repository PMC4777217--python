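"""Binary structure fingerprints for the structure map.

Any compounds x bits 0/1 matrix can feed the structure SOM; when SMILES
are available, hashed circular (Morgan) substructure fingerprints are
computed here via RDKit.  RDKit is an optional dependency (extra "chem").
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def fingerprints_from_smiles(
    smiles: Mapping[str, str] | Sequence[tuple[str, str]],
    n_bits: int = 1024,
    radius: int = 2,
) -> pd.DataFrame:
    """Hashed circular substructure fingerprints from SMILES strings.

    ``smiles`` maps compound id -> SMILES.  Unparseable SMILES raise a
    ValueError naming the compound.  Returns a compounds x n_bits 0/1
    DataFrame suitable for :func:`toxprofiler.som.train_som`.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "RDKit is required for SMILES fingerprints; "
            "install toxprofiler[chem]"
        ) from exc

    items = list(smiles.items()) if isinstance(smiles, Mapping) else list(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits
    )
    rows, index = [], []
    for cid, smi in items:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for compound {cid!r}: {smi!r}")
        fp = gen.GetFingerprint(mol)
        arr = np.zeros(n_bits, dtype=np.int8)
        for bit in fp.GetOnBits():
            arr[bit] = 1
        rows.append(arr)
        index.append(cid)
    return pd.DataFrame(
        rows, index=index, columns=[f"bit{j:04d}" for j in range(n_bits)]
    )
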