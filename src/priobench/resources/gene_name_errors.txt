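# Known gene-name error symbols, blocked before lexicon resolution.
# These are the spreadsheet/date-style symbol families that appear in model
# output and in corrupted supplementary tables but should never be credited
# as gene predictions, even where an alias of the same shape exists.
# Override with your own list via load_lexicon(..., error_list_path=...).
SEPT1
SEPT2
SEPT3
SEPT4
SEPT5
SEPT6
SEPT7
SEPT8
SEPT9
SEPT10
SEPT11
SEPT12
SEPT13
SEPT14
SEPT15
MARCH1
MARCH2
MARCH3
MARCH4
MARCH5
MARCH6
MARCH7
MARCH8
MARCH9
MARCH10
MARCH11
MARC1
MARC2
MAR1
MAR2
MAR3
MAR4
MAR5
MAR6
MAR7
MAR8
MAR9
MAR10
MAR11
DEC1
DEC2
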