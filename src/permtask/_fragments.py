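"""Fragment grammar for the synthetic molecule library.

Template strings with ``{r1}``/``{r2}`` substitution slots are combined with
substituent fragments and validated through RDKit at sampling time; ring
closure digit 9 is reserved for ring-bearing substituents so nesting never
clashes with core ring numbering.  The grammar spans aromatic/aliphatic
drug-like cores, macrocyclic lactams, short peptides and linker-joined
bifunctional (PROTAC-like) molecules, giving the size classes the modality
labels refer to.
"""

# small-molecule cores with one substitution slot
CORES_1 = [
    "c1ccc({r1})cc1",
    "c1ccc2cc({r1})ccc2c1",
    "c1ccnc({r1})c1",
    "c1cnc({r1})nc1",
    "c1ccc2[nH]c({r1})cc2c1",
    "c1ccc2[nH]c({r1})nc2c1",
    "c1cc({r1})sc1",
    "c1cc({r1})oc1",
    "C1CCN({r1})CC1",
    "C1COCCN1{r1}",
    "C1CCC({r1})CC1",
    "c1ccc(-c2ccc({r1})cc2)cc1",
    "O=S(=O)(N)c1ccc({r1})cc1",
    "O=C(N)c1ccc({r1})cc1",
]

# small-molecule cores with two substitution slots
CORES_2 = [
    "c1ccc({r1})c({r2})c1",
    "c1cc({r1})cc({r2})c1",
    "C1CN({r1})CCN1{r2}",
    "O=C(Nc1ccc({r1})cc1)c1ccc({r2})cc1",
    "O=C(Nc1ccc({r1})cc1)N({r2})C",
    "c1nc({r1})c2ccccc2n1{r2}",
    "O=C(N({r2})C)c1ccc({r1})cc1",
    "c1cc({r1})nc({r2})c1",
]

# substituents: valid as a parenthesised branch or as a suffix fragment
SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "C(F)(F)F", "C#N", "C(=O)O", "C(=O)N",
    "C(=O)OC", "S(C)(=O)=O", "CO", "CCO", "CN", "CCN(C)C", "C9CC9",
    "c9ccccc9", "c9ccncc9", "N9CCOCC9", "OC(F)F", "CC(=O)N",
]

# macrocycle ring units; a lactam ring is closed around 4-7 of them
MACROCYCLE_UNITS = ["C", "CC", "CCO", "CCN(C)", "CCOC", "CC(C)"]

# peptide side chains (None = glycine)
PEPTIDE_SIDE_CHAINS = [
    None, "C", "C(C)C", "CC(C)C", "Cc9ccccc9", "CO", "C(C)O", "CCSC",
    "CC(=O)N", "CCCCN", "CC(=O)O",
]

# bifunctional (PROTAC-like) molecule parts
PROTAC_HEADS = ["O=C(C)N", "O=S(=O)(C)N", "O=C(OC)N"]
PROTAC_LINKERS = [
    "CC", "CCC", "CCCC", "CCCCC", "CCOCC", "CCOCCOCC", "CCOCCOCCOCC",
    "CCOCCC", "CCCOCCC", "CCNC(=O)CC", "CCOCCOC", "CCCCCC", "CCOCCCC",
]
PROTAC_TAILS = ["C3CCCCC3", "C3CCNCC3", "C3CCOCC3", "C(C)(C)C", "CC(C)C", "C3CC3"]
PROTAC_TEMPLATE = (
    "{head}c1ccc(O{linker}Oc2ccc(C(=O)N{tail})cc2)cc1"
)
PROTAC_TEMPLATE_ME = (
    "{head}c1cc(C)c(O{linker}Oc2ccc(C(=O)N{tail})cc2)cc1"
)


def peptide_smiles(side_chains: list) -> str:
    """Linear peptide from N-terminus to the free acid."""
    parts = ["N"]
    for i, side in enumerate(side_chains):
        tail = "C(=O)O" if i == len(side_chains) - 1 else "C(=O)N"
        parts.append((f"C({side})" if side else "C") + tail)
    return "".join(parts)


def macrocycle_smiles(units: list[str], side: str | None = None) -> str:
    """Macrocyclic lactam closed over the given ring units."""
    body = "".join(units)
    if side:
        body += f"C({side})"
    return "O=C1" + body + "N1"
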