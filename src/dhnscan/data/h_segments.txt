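MAGIIHKIEETLHIG
MAGIIHKIEETLHMG
MAGIIHKIEEKLHIG
MAGIIHKIEEKLHMG
MAGIIHKIEEALHIG
MAGIIHKIEEALHMG
MSGIIHKIEETLHIG
MSGIIHKIEETLHMG
MSGIIHKIEEKLHIG
MSGIIHKIEEKLHMG
MSGIIHKIEEALHIG
MSGIIHKIEEALHMG
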