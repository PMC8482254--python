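cripplingalcoholism
vodka
oldtimehockey
alcohol
beer
bourbon
homebrewing
drinkinggames
wine
beercirclejerk
gin
scotch
liquor
showerbeer
absinthe
firewater
beercanada
drunk
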