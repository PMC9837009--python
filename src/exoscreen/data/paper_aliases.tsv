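# Pinned published variant ids for the default enumeration scheme.
# Only three of the twelve published ids are recoverable from the study's
# prose (A14C, G15C, G15U); the remaining internal ids have no known alias.
internal	published
7	5
11	6
12	7
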