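"""How filament damage phenotypes degrade automated picking.

Benchmarks the default pipeline on small seeded sets of simulated
micrographs for the three phenotypes micrograph inspection distinguishes:
healthy twisted filaments, "swollen" (blobby) filaments, and non-twisting
flat ribbons.  Ribbons project very weak contrast and largely vanish below
the picking threshold — consistent with such data sets defeating automated
picking in practice.

Run:  python examples/phenotype_benchmark.py   (about a minute)
"""

from helipick.benchmark import pick_benchmark

for phenotype in ("good", "swollen", "ribbon"):
    result = pick_benchmark(n_micrographs=5, seed=0, phenotype=phenotype)
    print(f"{phenotype:8s}  coverage {result.coverage:5.3f}  "
          f"precision {result.precision:5.3f}  "
          f"({result.n_traces} traces on {result.n_micrographs} micrographs)")
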