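"""Over-representation of a DEG list in gene-set collections (GMT).

Hypergeometric upper-tail test per set against the measured-gene universe,
with Benjamini-Hochberg FDR across sets.
"""

import tempfile
from pathlib import Path

import lsmsurv as L

# a small synthetic GMT collection: one set enriched in the DEGs, one not
gmt = Path(tempfile.mkdtemp()) / "sets.gmt"
gmt.write_text(
    "CELL_DIVISION\tsynthetic set\tG1\tG2\tG3\tG4\tG5\n"
    "UNRELATED\tsynthetic set\tG90\tG91\tG92\tG93\tG94\n"
)

universe = [f"G{i}" for i in range(1, 101)]
degs = ["G1", "G2", "G3", "G4", "G10", "G11"]

result = L.ora(degs, universe, L.read_gmt(gmt))
print(result.to_string(index=False))
# k of K set members among the n DEGs drawn from N universe genes; a small
# p_value means the overlap is larger than chance sampling would give.
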