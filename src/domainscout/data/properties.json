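{
  "name": "taylor-zvelebil-10",
  "version": 1,
  "comment": "Ten physicochemical residue classes of the Taylor Venn diagram as used by the AMAS/Jalview property-based conservation score.",
  "properties": [
    {"name": "hydrophobic", "members": "ACFGHIKLMTVWY"},
    {"name": "polar", "members": "CDEHKNQRSTWY"},
    {"name": "small", "members": "ACDGNPSTV"},
    {"name": "proline", "members": "P"},
    {"name": "tiny", "members": "AGS"},
    {"name": "aliphatic", "members": "ILV"},
    {"name": "aromatic", "members": "FHWY"},
    {"name": "positive", "members": "HKR"},
    {"name": "negative", "members": "DE"},
    {"name": "charged", "members": "DEHKR"}
  ]
}
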