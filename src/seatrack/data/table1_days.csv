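animal_id,location,species,days_tracked
652631A,Shoalwater Bay,dugong,141
652636A,Shoalwater Bay,dugong,51
652640A,Shoalwater Bay,dugong,6
652642A,Shoalwater Bay,dugong,34
652643A,Shoalwater Bay,dugong,54
96777,Shoalwater Bay,turtle,145
96780,Shoalwater Bay,turtle,121
108469,Shoalwater Bay,turtle,147
108472,Shoalwater Bay,turtle,148
120640,Shoalwater Bay,turtle,137
120641,Shoalwater Bay,turtle,131
641060A,Torres Strait,dugong,69
641058A,Torres Strait,dugong,33
641052A,Torres Strait,dugong,79
641054A,Torres Strait,dugong,30
641057A,Torres Strait,dugong,22
641055A,Torres Strait,dugong,7
70455,Torres Strait,turtle,134
95889,Torres Strait,turtle,27
95891,Torres Strait,turtle,28
95892,Torres Strait,turtle,47
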