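"""Parse a small Helium-dialect pedigree, validate it, traverse it and
augment it with selfing generations.

Prints entry/founder counts, the ancestry of one line, and the size of the
pedigree after inserting seven selfing generations below every cross (the
inbreeding model used throughout the kinship and simulation steps).
"""

from pedsel import (
    ancestors,
    augment_selfing,
    pedigree_from_text,
    pedigree_summary,
    validate_pedigree,
)

TEXT = """entry\tparent1\tparent2\tyear\tcountry\tlandrace
OldLandrace\t\t\t1880\tUK\t1
Squarehead\tOldLandrace\t\t1890\tUK\t0
Import\t\t\t1930\tFR\t0
MidCentury\tSquarehead\tImport\t1955\tUK\t0
Modern\tMidCentury\tImport\t2004\tUK\t0
"""

ped = pedigree_from_text(TEXT)
report = validate_pedigree(ped)
print(f"pedigree well-formed: {report.ok}")

s = pedigree_summary(ped, year_threshold=1900)
print(f"{s.n_entries} entries, {s.n_founders} founders, "
      f"{s.n_released_before} released before 1900")
print(f"countries: {s.per_country}")

anc = ancestors(ped, "Modern")
print(f"'Modern' has {len(anc)} known ancestors: {sorted(anc)}")

aug = augment_selfing(ped, generations=7)
print(f"augmented pedigree: {len(aug)} entries "
      f"({len(ped)} named + 7 selfing steps per cross)")
# Each cross now sits above an F1 and a chain of selfed intermediates, so
# kinship coefficients account for near-complete inbreeding of varieties.
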