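emma
liam
olivia
noah
ava
mason
sophia
lucas
mia
ethan
harper
logan
ella
jack
avery
aiden
scarlett
carter
grace
owen
chloe
wyatt
lily
luke
zoey
henry
nora
levi
hazel
caleb
violet
ryan
aurora
isaac
savannah
dylan
audrey
nathan
claire
eli
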