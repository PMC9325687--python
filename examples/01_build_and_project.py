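"""Build the lncRNA-disease association matrix from two edge lists.

Generates a small synthetic lncRNA-miRNA-disease network, assembles the two
binary adjacency layers, and projects them through the shared miRNA axis.
Entry (i, j) of the result counts the miRNAs that link lncRNA i to disease j;
a larger count means more independent molecular routes connect the pair.
"""

from encflda import SynthConfig, build_network, generate, project

net = generate(SynthConfig(n_l=12, n_m=8, n_d=6, rank=2, n_gold=5,
                           density_lm=0.25, density_md=0.25, seed=4))
a_lm, a_md = build_network(net.lm_pairs, net.md_pairs)
print(f"A_LM: {a_lm.shape[0]} lncRNAs x {a_lm.shape[1]} miRNAs, "
      f"{int(a_lm.values.sum())} interactions")
print(f"A_MD: {a_md.shape[0]} miRNAs x {a_md.shape[1]} diseases, "
      f"{int(a_md.values.sum())} associations")

a_ld = project(a_lm, a_md)
print(f"\nprojected A_LD = A_LM @ A_MD ({a_ld.shape[0]} x {a_ld.shape[1]}):")
print(a_ld.to_frame().astype(int).to_string())
print("\nEach entry counts shared miRNA neighbors; zero means no known "
      "molecular route between that lncRNA and disease.")
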