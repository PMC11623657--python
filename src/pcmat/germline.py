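"""Synthetic germline V-segment registry.

The simulator works in amino-acid space on sequences pre-aligned to germline
coordinates, so each germline V segment is a fixed-length residue string.
These segments are *synthetic analogs*: they carry the names of the mouse V
genes that dominate the anti-NP response, but their sequences are randomly
generated stand-ins, not IMGT alleles.  The only structural constraint is
that the high-affinity analog ``IGHV1-72*01`` carries W at position 33, K at
position 59 and Y at position 99 (1-based), so that the canonical
affinity-enhancing substitutions W33L, K59R and Y99G can arise by point
mutation, while the other heavy V genes carry different residues at those
positions and therefore cannot acquire them.
"""

from __future__ import annotations

HEAVY_V_LENGTH = 110
LIGHT_V_LENGTH = 100

#: heavy-chain V segments (aligned amino-acid strings, 110 residues)
HEAVY_V: dict[str, str] = {
    "IGHV1-72*01": (
        "VWKQNVVDIAGSVVKFMFILDMQFPCGAPKGWWCHWGFWFHMQEIGDKVYVGYRQ"
        "HWDKFSQQWRDWCMWCVSWIGEPGEPYHNWHQPIRDEWGCPINYAVDQRWKQCIW"
    ),
    "IGHV1-53*01": (
        "PLYMFDAQMDCQAIAAKYMGYAMCQMARYGKNMHRYVNSSNASTIFCHWIKIGHQ"
        "EIPVVVVWEVNRQLCHIQRSCLAHHISIMLIFKTFLTQSTGNYTGPLPGQPLITG"
    ),
    "IGHV9-3*01": (
        "YSQMEAKQAPTQMMIKVAKQIKLTYPCRASRRADCTGPKWNKEMAYRSWKGHKQC"
        "ATVRQMSQLWPVIQSIQKLWKWPSVNVMCFAWYCRIHCWTCFTPMNMGYRNWLKC"
    ),
    "IGHV5-17*01": (
        "NVFMEWRMSPWKLMQGDKRGQYWEITMCFVMGQLWENGYIYATIWWPWQLLPEWL"
        "QICFPQDFSTVYSPCIYTSDKSYIEPLRCPTMKAFRKYLTMHEVINQTREHQWRT"
    ),
}

#: light-chain (kappa) V segments (aligned amino-acid strings, 100 residues)
LIGHT_V: dict[str, str] = {
    "IGKV4-53*01": (
        "GIWCMICKEHIETIWRVRMLPRWSWFPETFTHWYGAINMTQVTCETNWIGPEYNQ"
        "YYYDIMFYKEFSFNWWVANPWAFINIFVQKLKECNAESSPGPALL"
    ),
    "IGKV5-48*01": (
        "QPPYWIDGRPPLQQGILGFYAELSFGGYSASIDQDQFYHSNRFCQDYICHLFMQK"
        "KLTNHGFTMMFKYQKKGVNPWAPDCYCHDINFPNPFWDVENIMIE"
    ),
    "IGKV17-127*01": (
        "WTNHQWSQWFVQIFADQGMQVDYWNKGMYQWCQDDTSVHSCCLGYMEYFYHFMYI"
        "SNCVLQYHELSFPYNYHHERRECTEVMFQPVDPAKHEFEEGMLMK"
    ),
}

HEAVY_J = ("IGHJ1*01", "IGHJ2*01", "IGHJ3*01", "IGHJ4*01")
LIGHT_J = ("IGKJ1*01", "IGKJ2*01", "IGKJ4*01", "IGKJ5*01")

#: every germline segment, keyed by v_call
GERMLINES: dict[str, str] = {**HEAVY_V, **LIGHT_V}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def germline_of(v_call: str) -> str:
    """Return the aligned germline string for a V call.

    Raises ``KeyError`` for unknown calls.
    """
    return GERMLINES[v_call]
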