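"""Fragment-ion mass arithmetic for one peptide.

Prints the b/y-family m/z ladder of a peptide and checks the b/y
complementarity identity: at every cut, mz(b) + mz(y) = M + 2 protons.
"""

from muxnovo.chem import H2O, ION_TYPES, PROTON, ResidueTable, fragment_mz

table = ResidueTable.default()
peptide = "PEPTIDE"
total = table.residue_sum(peptide)
neutral = total + H2O

print(f"peptide {peptide}: neutral monoisotopic mass {neutral:.5f} Da")
header = "cut  " + "".join(f"{ion.name:>10}" for ion in ION_TYPES)
print(header)
for i, pm in enumerate(table.prefix_masses(peptide)[:-1], start=1):
    row = f"{peptide[:i]:<5}" + "".join(
        f"{fragment_mz(pm, total, ion):10.4f}" for ion in ION_TYPES
    )
    print(row)

worst = max(
    abs(fragment_mz(pm, total, ION_TYPES[0]) + fragment_mz(pm, total, ION_TYPES[1])
        - (neutral + 2 * PROTON))
    for pm in table.prefix_masses(peptide)[:-1]
)
print(f"\nb/y complementarity worst deviation: {worst:.2e} Da")
# Each row is the m/z a mass spectrometer would observe for that fragment;
# complementary b/y pairs tile the precursor mass, which is what the beam
# search's precursor-mass filter exploits.
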