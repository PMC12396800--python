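# ICD-9 / ICD-10 billing codes treated as NID-related, one per line.
# A demo stand-in list covering bacterial/viral/fungal meningitis,
# encephalitis, and intracranial abscess codes.
G00.0
G00.1
G00.2
G00.3
G00.8
G00.9
G01
G02
G03.9
G04.2
G04.90
G05.3
G06.0
A17.0
A39.0
A85.8
A86
A87.0
A87.9
B00.3
B00.4
B01.0
B02.1
B45.1
B58.2
320.9
321.0
321.1
322.9
323.9
324.0
036.0
047.9
049.9
053.0
054.3
054.72
013.0
117.5
090.41
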