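"""Fingerprint generation from SMILES.

The default fingerprint is a hashed linear-path (topological) fingerprint
of 1024 bits: every linear atom-bond path of 1-7 bonds is enumerated and
hashed onto the bit vector.  This is the same family of fingerprint as
Open Babel's FP2; exact bit layouts differ between toolkits, but the
Tanimoto comparisons the pipeline makes only require that one consistent
path fingerprint is used for every drug in a library.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

DEFAULT_FP_BITS = 1024


def fingerprint_from_smiles(smiles: str, n_bits: int = DEFAULT_FP_BITS) -> np.ndarray:
    """Hashed linear-path fingerprint (1-7 bond paths) of a SMILES string."""
    from rdkit import Chem  # imported lazily: only SMILES input needs it

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES: {smiles!r}")
    fp = Chem.RDKFingerprint(mol, minPath=1, maxPath=7, fpSize=n_bits)
    return np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8) == ord("1")


def fingerprint_to_hex(fp: np.ndarray) -> str:
    """Serialize a boolean fingerprint as big-endian packed-bit hex."""
    return np.packbits(np.asarray(fp, dtype=bool)).tobytes().hex()


def fingerprint_from_hex(text: str, length: int) -> np.ndarray:
    """Inverse of :func:`fingerprint_to_hex` for a known bit length."""
    raw = np.frombuffer(bytes.fromhex(text), dtype=np.uint8)
    bits = np.unpackbits(raw)
    if bits.size < length:
        raise ValidationError(
            f"hex fingerprint holds {bits.size} bits, expected {length}"
        )
    return bits[:length].astype(bool)
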