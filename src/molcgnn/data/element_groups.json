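{
  "group_names": ["Metals", "Metalloids", "Halogens", "Carbon", "Nitrogen", "Oxygen", "Phosphorus", "Sulfur"],
  "groups": {
    "Metals": ["Li", "Be", "Na", "Mg", "Al", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Ga", "Rb", "Sr", "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn", "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb", "Bi", "Fr", "Ra", "Ac", "Th", "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm", "Md", "No", "Lr"],
    "Metalloids": ["B", "Si", "Ge", "As", "Sb", "Te", "Se", "Po"],
    "Halogens": ["F", "Cl", "Br", "I", "At"],
    "Carbon": ["C"],
    "Nitrogen": ["N"],
    "Oxygen": ["O"],
    "Phosphorus": ["P"],
    "Sulfur": ["S"]
  }
}
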