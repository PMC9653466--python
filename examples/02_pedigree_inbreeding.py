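"""Relationship matrix and inbreeding on a textbook mating design.

Two founders, two full-sib offspring, and a lamb bred from the full sibs:
the lamb's inbreeding coefficient must be 0.25, and Wright's path-counting
formula must agree with the recursive computation.
"""

import numpy as np

from flockgen import amatrix, ainverse, build_pedigree, inbreeding, inbreeding_wright

ped = build_pedigree([
    ("SIRE", None, None), ("DAM", None, None),
    ("SIB1", "SIRE", "DAM"), ("SIB2", "SIRE", "DAM"),
    ("LAMB", "SIB1", "SIB2"),
])
A = amatrix(ped)
F = inbreeding(ped)

print("animals:", ped.ids)
print("A matrix:")
print(np.round(A, 3))
print("inbreeding F:", dict(zip(ped.ids, np.round(F, 3))))
print("Wright path formula for LAMB:", inbreeding_wright(ped, "LAMB"))
# F = 0.25: the full-sib parents share both founders, two paths of two
# segregations each, 2 * (1/2)^3 = 0.25

prod = A @ ainverse(ped, F).toarray()
print("max |A A^-1 - I| =", np.abs(prod - np.eye(len(ped))).max())
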