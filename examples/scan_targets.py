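"""Scan transcripts for miRNA target sites by complementarity penalty.

Every window the length of the miRNA is scored antiparallel against it:
mismatch 1.0, G:U wobble 0.5, doubled at miRNA positions 2-13; windows
with penalty <= 4.0 are reported.  Positional flags mark mismatches at
positions 10-11 (cleavage site) or >1 mismatch in positions 2-12.
"""

import random

from mirflow._util import revcomp
from mirflow.targets import scan_transcripts

rng = random.Random(0)
mirna = "TGGAGCTCCCTTCATTCCAAT"
perfect = revcomp(mirna)
near = perfect[:6] + "A" + perfect[7:]  # one disruption

body = "".join(rng.choice("ACGT") for _ in range(600))
transcripts = {
    "tx1": body[:200] + perfect + body[200:],
    "tx2": body[300:] + near + body[:150],
}

sites = scan_transcripts("mir156-like", mirna, transcripts, max_penalty=4.0)
for s in sites:
    print(f"{s.transcript_id}:{s.start}-{s.end}  penalty={s.penalty}  flags={s.flags or '-'}")
    mir_row, pairing, target = s.alignment
    print(f"   miRNA 3'-{mir_row}-5'")
    print(f"            {pairing}")
    print(f"  target 5'-{target}-3'")

# Penalty 0 is a perfect site; the disrupted copy scores the mismatch
# (doubled if it falls in the 2-13 core) and sorts after it.
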