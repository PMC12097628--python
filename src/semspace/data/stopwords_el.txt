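# Frozen Greek stopword list (articles, pronouns, particles, common
# function words), one per line. Shipped as package data so tokenization
# does not drift with external package versions.
ο
η
το
οι
τα
του
της
των
τον
την
και
κι
κ
ειμαι
εισαι
ειναι
ειμαστε
ειστε
στο
στον
στη
στην
μα
αλλα
απο
για
προς
με
σε
ως
παρα
αντι
κατα
μετα
θα
να
δε
δεν
μη
μην
επι
ενω
εαν
αν
τοτε
που
πως
ποιος
ποια
ποιο
ποιοι
ποιες
ποιων
ποιους
αυτος
αυτη
αυτο
αυτοι
αυτες
αυτα
αυτων
αυτους
εκεινος
εκεινη
εκεινο
εκεινοι
εκεινες
εκεινα
εγω
εσυ
εμεις
εσεις
εμενα
εσενα
μου
σου
μας
σας
τους
τις
τι
τις
οτι
οταν
οπου
οπως
ομως
ουτε
η
ειτε
καθε
καθως
μεσα
εξω
πανω
κατω
εδω
εκει
τωρα
μετα
πριν
παλι
ακομα
ακομη
ολος
ολη
ολο
ολοι
ολες
ολα
πολυ
πολλα
λιγο
πιο
πια
κατι
τιποτα
κανεις
καμια
κανενα
ενας
μια
ενα
δυο
σαν
λοιπον
δηλαδη
γιατι
επειδη
αφου
ωστε
στα
στις
στους
τη
τις
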