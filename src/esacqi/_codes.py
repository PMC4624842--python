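"""Bundled J01 (antibacterials for systemic use) ATC code list.

A representative subset of the WHO ATC index sufficient for the
prescribing-quality group map and the synthetic cohort generator; it is
not a complete registry.  DDD volumes arrive pre-aggregated in the input
records, so no per-code DDD values are needed.
"""

# code -> substance (levels 5 and 7 mixed on purpose: ingest must accept both)
J01_CODES: dict[str, str] = {
    # tetracyclines
    "J01AA02": "doxycycline",
    "J01AA08": "minocycline",
    # penicillins with extended spectrum (aminopenicillins)
    "J01CA01": "ampicillin",
    "J01CA04": "amoxicillin",
    # beta-lactamase-sensitive penicillins
    "J01CE02": "phenoxymethylpenicillin",
    "J01CE10": "benzathine phenoxymethylpenicillin",
    # beta-lactamase-resistant penicillins
    "J01CF02": "cloxacillin",
    # combinations of penicillins incl. beta-lactamase inhibitors
    "J01CR02": "amoxicillin and beta-lactamase inhibitor",
    "J01CR05": "piperacillin and beta-lactamase inhibitor",
    # first-generation cephalosporins
    "J01DB01": "cefalexin",
    "J01DB05": "cefadroxil",
    # second-generation cephalosporins
    "J01DC02": "cefuroxime",
    "J01DC04": "cefaclor",
    # third-generation cephalosporins
    "J01DD04": "ceftriaxone",
    "J01DD08": "cefixime",
    "J01DD14": "ceftibuten",
    # fourth-generation cephalosporins
    "J01DE01": "cefepime",
    # sulfonamide/trimethoprim
    "J01EA01": "trimethoprim",
    "J01EE01": "sulfamethoxazole and trimethoprim",
    # macrolides
    "J01FA01": "erythromycin",
    "J01FA02": "spiramycin",
    "J01FA06": "roxithromycin",
    "J01FA09": "clarithromycin",
    "J01FA10": "azithromycin",
    "J01FA15": "telithromycin",
    # lincosamides
    "J01FF01": "clindamycin",
    # aminoglycosides
    "J01GB03": "gentamicin",
    # fluoroquinolones
    "J01MA01": "ofloxacin",
    "J01MA02": "ciprofloxacin",
    "J01MA06": "norfloxacin",
    "J01MA12": "levofloxacin",
    "J01MA14": "moxifloxacin",
    # other quinolones
    "J01MB04": "pipemidic acid",
    # other antibacterials
    "J01XE01": "nitrofurantoin",
    "J01XX01": "fosfomycin",
}
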