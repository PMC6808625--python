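"""Inspect the three lexical feature channels on a sentence.

Each token gets a POS one-hot, a gazetteer-membership flag and a
drug-affix flag; these are concatenated (raw, untrainable) onto the
character-enhanced token embedding before the token BiLSTM.
"""
from pathlib import Path

import pharmaconer as ph

work = Path("scratch/example-features")
work.mkdir(parents=True, exist_ok=True)
(work / "gazetteer.txt").write_text(
    "indometacina\nácido acetilsalicílico\n", encoding="utf-8")
(work / "affixes.tsv").write_text(
    "type\taffix_en\taffix_es\texample_en\tdrug_class\n"
    "suffix\t-caine\t-caína\tlidocaine\tlocal anesthetic\n"
    "prefix\tcef-\tcef-\tcefazolin\tcephalosporin\n", encoding="utf-8")

gazetteer = ph.load_gazetteer(work / "gazetteer.txt")
affixes = ph.load_affixes(work / "affixes.tsv")

sentence = "Se administró lidocaína, indometacina y ácido acetilsalicílico."
print(f"{'token':<20}{'gazetteer':>10}{'affix':>7}")
for token in ph.tokenize(sentence):
    print(f"{token.surface:<20}"
          f"{ph.gazetteer_feature(token, gazetteer):>10}"
          f"{ph.affix_match(token, affixes):>7}")

# "lidocaína" fires the affix channel (suffix -caína, local anesthetics);
# "indometacina" is in the dictionary; the multi-word gazetteer entry
# fires per component word ("ácido", "acetilsalicílico") because lookup
# is per token.
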